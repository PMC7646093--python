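<?xml version="1.0" encoding="UTF-8"?>
<!--
  SYNTHETIC structural subset of the TraML 1.0.0 schema, hand-written for
  offline validation of the TraML documents this package emits.  It is NOT
  the official PSI TraML1.0.0.xsd: it covers the element hierarchy, required
  attributes and controlled-vocabulary parameter structure used here
  (cvList, CompoundList/Peptide with retention times, TransitionList with
  Precursor/Product m/z), not the full standard.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:traml="http://psi.hupo.org/ms/traml"
           targetNamespace="http://psi.hupo.org/ms/traml"
           elementFormDefault="qualified">

  <xs:complexType name="cvParamType">
    <xs:attribute name="cvRef" type="xs:string" use="required"/>
    <xs:attribute name="accession" type="xs:string" use="required"/>
    <xs:attribute name="name" type="xs:string" use="required"/>
    <xs:attribute name="value" type="xs:string" use="optional"/>
    <xs:attribute name="unitCvRef" type="xs:string" use="optional"/>
    <xs:attribute name="unitAccession" type="xs:string" use="optional"/>
    <xs:attribute name="unitName" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="cvType">
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="fullName" type="xs:string" use="required"/>
    <xs:attribute name="version" type="xs:string" use="optional"/>
    <xs:attribute name="URI" type="xs:anyURI" use="required"/>
  </xs:complexType>

  <xs:complexType name="cvListType">
    <xs:sequence>
      <xs:element name="cv" type="traml:cvType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="retentionTimeType">
    <xs:sequence>
      <xs:element name="cvParam" type="traml:cvParamType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="retentionTimeListType">
    <xs:sequence>
      <xs:element name="RetentionTime" type="traml:retentionTimeType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="peptideType">
    <xs:sequence>
      <xs:element name="cvParam" type="traml:cvParamType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="RetentionTimeList" type="traml:retentionTimeListType" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="sequence" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="compoundListType">
    <xs:sequence>
      <xs:element name="Peptide" type="traml:peptideType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="ionType">
    <xs:sequence>
      <xs:element name="cvParam" type="traml:cvParamType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="transitionType">
    <xs:sequence>
      <xs:element name="Precursor" type="traml:ionType" minOccurs="0"/>
      <xs:element name="Product" type="traml:ionType"/>
      <xs:element name="cvParam" type="traml:cvParamType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="peptideRef" type="xs:IDREF" use="required"/>
  </xs:complexType>

  <xs:complexType name="transitionListType">
    <xs:sequence>
      <xs:element name="Transition" type="traml:transitionType" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:element name="TraML">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="cvList" type="traml:cvListType"/>
        <xs:element name="CompoundList" type="traml:compoundListType" minOccurs="0"/>
        <xs:element name="TransitionList" type="traml:transitionListType" minOccurs="0"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
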