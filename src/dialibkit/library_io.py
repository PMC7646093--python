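"""Library serialization, merge/subset, and PRM schedule export.

The canonical on-disk form is the OpenSWATH transition TSV (one row per
transition); TraML 1.0 XML is provided for transition lists and landmark
sets.  ``Tr_recalibrated`` carries iRT (dimensionless); the raw best RT is
kept in an optional column.  PRM inclusion lists use minutes, the
instrument convention, while everything internal is in seconds.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
from lxml import etree

from .assays import AssayEntry, Library, Transition
from .chem import FragmentIon, PrecursorKey, parse_modified_sequence
from .landmarks import CalibrationFit, LandmarkSet, invert_calibration

__all__ = [
    "OPENSWATH_COLUMNS",
    "PRMScheduleConfig",
    "LibraryParseError",
    "write_openswath_tsv",
    "read_openswath_tsv",
    "write_traml",
    "validate_traml",
    "export_prm_schedule",
    "merge_libraries",
    "subset_library",
]

OPENSWATH_COLUMNS = [
    "PrecursorMz",
    "ProductMz",
    "Tr_recalibrated",
    "transition_name",
    "LibraryIntensity",
    "decoy",
    "PeptideSequence",
    "FullUniModPeptideName",
    "PrecursorCharge",
    "ProteinName",
    "FragmentType",
    "FragmentCharge",
    "FragmentSeriesNumber",
]

# extra columns kept so that write -> read is the identity on entries
_EXTRA_COLUMNS = ["NReplicates", "SampleType", "BestScore", "TargetGroupId"]


class LibraryParseError(ValueError):
    """A transition TSV row could not be interpreted."""


@dataclass(frozen=True)
class PRMScheduleConfig:
    rt_halfwidth_minutes: float = 5.0
    max_concurrent_precursors: int = 100
    include_transitions: bool = False

    def __post_init__(self) -> None:
        if self.rt_halfwidth_minutes <= 0:
            raise ValueError("rt_halfwidth_minutes must be positive")
        if self.max_concurrent_precursors < 1:
            raise ValueError("max_concurrent_precursors must be >= 1")


def write_openswath_tsv(library: Library, path) -> None:
    """One row per transition, OpenSWATH column dialect."""
    rows = []
    for entry in library.entries:
        for t in entry.transitions:
            rows.append(
                {
                    "PrecursorMz": repr(t.precursor_mz),
                    "ProductMz": repr(t.product_mz),
                    "Tr_recalibrated": repr(t.irt),
                    "transition_name": t.transition_name,
                    "LibraryIntensity": repr(t.library_intensity),
                    "decoy": 1 if t.is_decoy else 0,
                    "PeptideSequence": t.peptide.sequence,
                    "FullUniModPeptideName": t.peptide.to_unimod_string(),
                    "PrecursorCharge": t.charge,
                    "ProteinName": ";".join(t.proteins),
                    "FragmentType": t.annotation.series,
                    "FragmentCharge": t.annotation.charge,
                    "FragmentSeriesNumber": t.annotation.ordinal,
                    "NReplicates": entry.n_replicates,
                    "SampleType": entry.sample_type,
                    "BestScore": repr(entry.best_score),
                    "TargetGroupId": entry.target_group_id,
                }
            )
    pd.DataFrame(rows, columns=OPENSWATH_COLUMNS + _EXTRA_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_openswath_tsv(path) -> Library:
    """Inverse of :func:`write_openswath_tsv`; unknown extra columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in OPENSWATH_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryParseError(f"missing column(s): {missing}")
    groups: dict[tuple, list[tuple[int, dict]]] = {}
    for i, row in enumerate(df.to_dict("records")):
        try:
            gk = (row["FullUniModPeptideName"], int(row["PrecursorCharge"]), int(row["decoy"]))
        except ValueError as exc:
            raise LibraryParseError(f"line {i + 2}: {exc}") from exc
        groups.setdefault(gk, []).append((i, row))
    entries = []
    for (full_name, charge, decoy), rows in groups.items():
        try:
            peptide = parse_modified_sequence(full_name)
            key = PrecursorKey(peptide, charge)
            transitions = []
            for i, row in rows:
                mz = float(row["ProductMz"])
                transitions.append(
                    Transition(
                        precursor_mz=float(row["PrecursorMz"]),
                        product_mz=mz,
                        library_intensity=float(row["LibraryIntensity"]),
                        annotation=FragmentIon(
                            row["FragmentType"],
                            int(row["FragmentSeriesNumber"]),
                            int(row["FragmentCharge"]),
                            mz,
                        ),
                        irt=float(row["Tr_recalibrated"]),
                        is_decoy=bool(decoy),
                        transition_name=row["transition_name"],
                        peptide=peptide,
                        charge=charge,
                        proteins=tuple(p for p in row["ProteinName"].split(";") if p),
                    )
                )
            first = rows[0][1]
            entries.append(
                AssayEntry(
                    key=key,
                    transitions=transitions,
                    irt=float(first["Tr_recalibrated"]),
                    proteins=tuple(p for p in first["ProteinName"].split(";") if p),
                    is_decoy=bool(decoy),
                    n_replicates=int(first.get("NReplicates", 1) or 1),
                    sample_type=first.get("SampleType", ""),
                    best_score=float(first.get("BestScore") or "nan"),
                    target_group_id=first.get("TargetGroupId", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise LibraryParseError(
                f"line {rows[0][0] + 2}: cannot parse assay {full_name}/{charge}: {exc}"
            ) from exc
    return Library(entries)


# --- TraML ------------------------------------------------------------------

_TRAML_NS = "http://psi.hupo.org/ms/traml"


def _cv_param(parent, accession: str, name: str, value: Optional[str] = None, cv_ref: str = "MS") -> None:
    attrs = {"cvRef": cv_ref, "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = value
    etree.SubElement(parent, f"{{{_TRAML_NS}}}cvParam", attrs)


def write_traml(obj: Library | LandmarkSet, path) -> None:
    """Write a library or landmark set as TraML 1.0 XML.

    Landmark sets export one peptide per landmark with its normalized RT;
    libraries export peptides plus their transitions with product ion
    intensities and target/decoy annotation.
    """
    nsmap = {None: _TRAML_NS}
    root = etree.Element(f"{{{_TRAML_NS}}}TraML", {"version": "1.0.0"}, nsmap=nsmap)
    cv_list = etree.SubElement(root, f"{{{_TRAML_NS}}}cvList")
    etree.SubElement(
        cv_list,
        f"{{{_TRAML_NS}}}cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "http://purl.obolibrary.org/obo/ms.obo",
        },
    )
    etree.SubElement(
        cv_list,
        f"{{{_TRAML_NS}}}cv",
        {
            "id": "UO",
            "fullName": "Unit Ontology",
            "URI": "http://purl.obolibrary.org/obo/uo.obo",
        },
    )

    if isinstance(obj, LandmarkSet):
        peptides = [
            (
                f"pep_{i}",
                lm.key,
                lm.reference_irt,
                (),
            )
            for i, lm in enumerate(obj.landmarks)
        ]
        transitions: list[tuple[str, str, Transition]] = []
    else:
        peptides = []
        transitions = []
        for i, entry in enumerate(obj.entries):
            pid = f"pep_{i}"
            peptides.append((pid, entry.key, entry.irt, entry.proteins))
            for j, t in enumerate(entry.transitions):
                transitions.append((f"tr_{i}_{j}", pid, t))

    compound_list = etree.SubElement(root, f"{{{_TRAML_NS}}}CompoundList")
    for pid, key, irt, _proteins in peptides:
        pep_el = etree.SubElement(
            compound_list,
            f"{{{_TRAML_NS}}}Peptide",
            {"id": pid, "sequence": key.peptide.sequence},
        )
        _cv_param(pep_el, "MS:1000041", "charge state", str(key.charge))
        _cv_param(pep_el, "MS:1000888", "stripped peptide sequence", key.peptide.sequence)
        if irt is not None:
            rt_list = etree.SubElement(pep_el, f"{{{_TRAML_NS}}}RetentionTimeList")
            rt_el = etree.SubElement(rt_list, f"{{{_TRAML_NS}}}RetentionTime")
            _cv_param(rt_el, "MS:1000896", "normalized retention time", repr(float(irt)))

    if transitions:
        tr_list = etree.SubElement(root, f"{{{_TRAML_NS}}}TransitionList")
        for tid, pid, t in transitions:
            tr_el = etree.SubElement(
                tr_list,
                f"{{{_TRAML_NS}}}Transition",
                {"id": tid, "peptideRef": pid},
            )
            prec = etree.SubElement(tr_el, f"{{{_TRAML_NS}}}Precursor")
            _cv_param(prec, "MS:1000827", "isolation window target m/z", repr(t.precursor_mz))
            prod = etree.SubElement(tr_el, f"{{{_TRAML_NS}}}Product")
            _cv_param(prod, "MS:1000827", "isolation window target m/z", repr(t.product_mz))
            _cv_param(tr_el, "MS:1001226", "product ion intensity", repr(t.library_intensity))
            if t.is_decoy:
                _cv_param(tr_el, "MS:1002008", "decoy SRM transition")
            else:
                _cv_param(tr_el, "MS:1002007", "target SRM transition")
    etree.ElementTree(root).write(
        os.fspath(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def validate_traml(path) -> None:
    """Validate a TraML file against the bundled structural schema.

    The schema is a hand-written structural subset of TraML 1.0.0 (see
    ``data/traml_subset_synthetic.xsd``); it checks the element hierarchy,
    required attributes and cvParam structure this package emits.
    Raises ``lxml.etree.DocumentInvalid`` on failure.
    """
    xsd_path = importlib.resources.files("dialibkit").joinpath(
        "data/traml_subset_synthetic.xsd"
    )
    with importlib.resources.as_file(xsd_path) as p:
        schema = etree.XMLSchema(etree.parse(os.fspath(p)))
    doc = etree.parse(os.fspath(path))
    schema.assertValid(doc)


# --- PRM schedule -----------------------------------------------------------


def export_prm_schedule(
    library: Library,
    targets: Sequence[str],
    fit: CalibrationFit,
    config: PRMScheduleConfig = PRMScheduleConfig(),
    path=None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Build a time-scheduled PRM inclusion list for the requested peptides.

    ``targets`` are peptide sequences (stripped or UniMod notation).  Each
    matching target precursor gets a window of predicted RT (inverse of the
    calibration fit, minutes) ± the configured halfwidth.  Returns the
    schedule, the list of requested peptides absent from the library, and
    concurrency warnings.
    """
    wanted = set(targets)
    rows = []
    found: set[str] = set()
    for entry in library.targets:
        seq = entry.key.peptide.sequence
        full = entry.key.peptide.to_unimod_string()
        hit = ({seq, full} & wanted)
        if not hit:
            continue
        found |= hit
        center_min = invert_calibration(entry.irt, fit) / 60.0
        row = {
            "Mass [m/z]": round(entry.key.mz, 5),
            "z": entry.key.charge,
            "Start [min]": round(center_min - config.rt_halfwidth_minutes, 3),
            "End [min]": round(center_min + config.rt_halfwidth_minutes, 3),
            "Polarity": "Positive",
            "Comment": f"{full}/{entry.key.charge} {';'.join(entry.proteins)}",
        }
        if config.include_transitions:
            row["Transitions"] = ";".join(
                f"{t.annotation.label}:{t.product_mz:.4f}" for t in entry.transitions
            )
        rows.append(row)
    missing = sorted(wanted - found)
    schedule = pd.DataFrame(rows)
    warnings: list[str] = []
    if len(schedule):
        events = []
        for _, r in schedule.iterrows():
            events.append((r["Start [min]"], 1))
            events.append((r["End [min]"], -1))
        events.sort()
        concurrent = peak = 0
        for _, delta in events:
            concurrent += delta
            peak = max(peak, concurrent)
        if peak > config.max_concurrent_precursors:
            warnings.append(
                f"up to {peak} concurrent precursors exceed the scheduling "
                f"capacity of {config.max_concurrent_precursors}"
            )
    if path is not None:
        schedule.to_csv(path, sep="\t", index=False)
    return schedule, missing, warnings


# --- merge / subset ---------------------------------------------------------


def merge_libraries(
    libraries: Sequence[Library], conflict_rule: str = "higher_best_score"
) -> Library:
    """Merge libraries keyed on precursor; decoys follow their targets.

    ``conflict_rule``: ``higher_best_score`` (default), ``more_replicates``
    or ``keep_first``.
    """
    if conflict_rule not in ("higher_best_score", "more_replicates", "keep_first"):
        raise ValueError(f"unknown conflict rule {conflict_rule!r}")
    if not libraries:
        raise ValueError("merge needs at least one library")
    chosen: dict[str, AssayEntry] = {}
    decoy_by_target: dict[str, AssayEntry] = {}
    order: list[str] = []
    for lib in libraries:
        local_decoys = {d.target_group_id: d for d in lib.decoys if d.target_group_id}
        for entry in lib.targets:
            gid = entry.group_id
            if gid not in chosen:
                chosen[gid] = entry
                order.append(gid)
                if gid in local_decoys:
                    decoy_by_target[gid] = local_decoys[gid]
                continue
            incumbent = chosen[gid]
            if conflict_rule == "keep_first":
                continue
            if conflict_rule == "higher_best_score":
                better = entry.best_score > incumbent.best_score
            else:
                better = entry.n_replicates > incumbent.n_replicates
            if better:
                chosen[gid] = entry
                if gid in local_decoys:
                    decoy_by_target[gid] = local_decoys[gid]
                elif gid in decoy_by_target:
                    del decoy_by_target[gid]
    entries = [chosen[g] for g in order]
    entries += [decoy_by_target[g] for g in order if g in decoy_by_target]
    meta = {"merged_from": len(libraries), "conflict_rule": conflict_rule}
    return Library(entries, metadata=meta)


def subset_library(
    library: Library,
    predicate: Optional[Callable[[AssayEntry], bool]] = None,
    sample_types: Optional[Iterable[str]] = None,
    proteins: Optional[Iterable[str]] = None,
    peptides: Optional[Iterable[str]] = None,
) -> Library:
    """Keep target entries matching all given criteria; a decoy survives iff
    its target does."""
    sample_set = set(sample_types) if sample_types is not None else None
    protein_set = set(proteins) if proteins is not None else None
    peptide_set = set(peptides) if peptides is not None else None

    def keep(entry: AssayEntry) -> bool:
        if predicate is not None and not predicate(entry):
            return False
        if sample_set is not None and entry.sample_type not in sample_set:
            return False
        if protein_set is not None and not (set(entry.proteins) & protein_set):
            return False
        if peptide_set is not None and not (
            {entry.key.peptide.sequence, entry.key.peptide.to_unimod_string()}
            & peptide_set
        ):
            return False
        return True

    kept_targets = [e for e in library.targets if keep(e)]
    kept_ids = {e.group_id for e in kept_targets}
    kept_decoys = [d for d in library.decoys if d.target_group_id in kept_ids]
    meta = dict(library.metadata)
    meta["subset_of"] = meta.get("n_targets", len(library.targets))
    return Library(kept_targets + kept_decoys, metadata=meta)
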