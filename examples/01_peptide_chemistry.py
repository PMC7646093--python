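"""Peptide chemistry basics: masses, precursor m/z, fragment annotation.

ESDTSYVSLK is a tryptic peptide of C-reactive protein (CRP, UniProtKB
P02741), a plasma inflammation marker often validated by targeted MS.
"""

from dialibkit import (
    ModifiedPeptide,
    Peak,
    Spectrum,
    annotate_fragments,
    match_peaks,
    monoisotopic_mass,
    parse_modified_sequence,
    precursor_mz,
)

pep = parse_modified_sequence("ESDTSYVSLK")
print(f"peptide            {pep.sequence}")
print(f"monoisotopic mass  {monoisotopic_mass(pep):.4f} Da")
print(f"precursor m/z 2+   {precursor_mz(pep, 2):.2f} Th")
# 564.77 Th is what the instrument shows when this peptide is scheduled for
# PRM at charge 2.

mod = parse_modified_sequence("C[UniMod:4]AVLIK")
print(f"\n{mod.to_unimod_string()}: carbamidomethyl adds "
      f"{monoisotopic_mass(mod) - monoisotopic_mass(ModifiedPeptide('CAVLIK')):.6f} Da")

ions = annotate_fragments(pep, max_fragment_charge=2)
print(f"\n{len(ions)} b/y ions at charge 1-2 (9 ordinals x 2 series x 2 charges)")
y1 = next(i for i in ions if i.label == "y1^1")
print(f"y1^1 = {y1.mz:.4f} Th (C-terminal K + water + proton)")

# match a tiny synthetic spectrum against the annotation with the 0.03 Th
# tolerance used for DIA extraction
spec = Spectrum(peaks=[Peak(y1.mz + 0.01, 120.0), Peak(400.0, 55.0)])
matched = match_peaks(spec, ions, tol=0.03)
print(f"matched {len(matched)} of {len(spec.peaks)} peaks "
      f"({next(iter(matched)).label} within ±0.03 Th)")
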