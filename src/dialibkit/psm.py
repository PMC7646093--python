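"""Reading, validating and filtering peptide-spectrum-match tables.

Search results arrive as tab-separated tables in one of three dialects
(generic, pFind-style export, MaxQuant ``peptides.txt`` subset).  On ingest
every retention time is normalised to seconds and every modification string
to UniMod bracket notation, so downstream stages see a single schema.
PSM-level FDR is assumed to be controlled by the upstream search engine; a
score cut is available but off by default.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .chem import ModifiedPeptide, Peak, PrecursorKey, Spectrum, parse_modified_sequence

__all__ = [
    "PSMRecord",
    "PSMTable",
    "SchemaError",
    "SpectraPairingError",
    "FilterReport",
    "AttachResult",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "read_spectra",
    "attach_spectra",
]


class SchemaError(ValueError):
    """A required column is missing from a PSM table."""


class SpectraPairingError(RuntimeError):
    """No PSM scan id could be resolved in the spectra source."""


@dataclass(frozen=True)
class PSMRecord:
    scan_id: str
    rt_seconds: float
    peptide: ModifiedPeptide
    charge: int
    proteins: tuple[str, ...]
    score: float
    precursor_intensity: Optional[float] = None
    run_id: str = "run0"
    sample_type: str = ""
    prev_aa: Optional[str] = None
    next_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("PSM must carry at least one protein accession")
        if self.rt_seconds < 0:
            raise ValueError("retention time must be non-negative")

    @property
    def key(self) -> PrecursorKey:
        return PrecursorKey(self.peptide, self.charge)


@dataclass
class PSMTable:
    records: list[PSMRecord]
    gradient_seconds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        span: dict[str, float] = {}
        for rec in self.records:
            span[rec.run_id] = max(span.get(rec.run_id, 0.0), rec.rt_seconds)
        for run_id, s in span.items():
            self.gradient_seconds.setdefault(run_id, s)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.gradient_seconds)


@dataclass
class FilterReport:
    table: PSMTable
    removed: dict[str, int]


@dataclass
class AttachResult:
    pairs: list[tuple[PSMRecord, Spectrum]]
    unmatched: list[PSMRecord]


_GENERIC_REQUIRED = ["scan_id", "rt_seconds", "sequence", "charge", "proteins", "score"]
_PFIND_REQUIRED = ["File_Name", "Scan_No", "Sequence", "Charge", "Final_Score", "Proteins", "RT"]
_MAXQUANT_REQUIRED = ["Sequence", "Proteins", "Charges", "Retention time", "Intensity", "Score"]


def read_psm_table(path: str | os.PathLike, dialect: str = "generic") -> PSMTable:
    """Read a TSV of PSMs into a :class:`PSMTable`.

    dialect ``generic``: columns scan_id, run_id, rt_seconds, sequence
    (UniMod notation), charge, proteins (``;``-separated), score, and
    optionally precursor_intensity, sample_type, prev_aa, next_aa.

    dialect ``pfind-style``: File_Name, Scan_No, Sequence, Charge,
    Final_Score, Proteins (``/``-separated), RT (seconds), optional
    Modification, Intensity.

    dialect ``maxquant-peptides``: the ``peptides.txt`` subset Sequence,
    Proteins, Charges, Retention time (minutes), Intensity, Score.

    Unparseable rows are skipped and counted (``table.skipped``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "generic":
        required = _GENERIC_REQUIRED
    elif dialect == "pfind-style":
        required = _PFIND_REQUIRED
    elif dialect == "maxquant-peptides":
        required = _MAXQUANT_REQUIRED
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) for {dialect}: {missing}")

    records: list[PSMRecord] = []
    skipped = 0
    for i, row in df.iterrows():
        try:
            records.append(_row_to_record(row, dialect, i))
        except Exception:
            skipped += 1
    table = PSMTable(records)
    table.skipped = skipped  # type: ignore[attr-defined]
    return table


def _row_to_record(row: pd.Series, dialect: str, idx: int) -> PSMRecord:
    if dialect == "generic":
        return PSMRecord(
            scan_id=row["scan_id"],
            rt_seconds=float(row["rt_seconds"]),
            peptide=parse_modified_sequence(row["sequence"]),
            charge=int(row["charge"]),
            proteins=tuple(p for p in row["proteins"].split(";") if p),
            score=float(row["score"]),
            precursor_intensity=_opt_float(row.get("precursor_intensity", "")),
            run_id=row.get("run_id", "run0") or "run0",
            sample_type=row.get("sample_type", ""),
            prev_aa=row.get("prev_aa") or None,
            next_aa=row.get("next_aa") or None,
        )
    if dialect == "pfind-style":
        seq = row["Sequence"]
        mod = row.get("Modification", "")
        text = _apply_pfind_mods(seq, mod)
        return PSMRecord(
            scan_id=str(row["Scan_No"]),
            rt_seconds=float(row["RT"]),
            peptide=parse_modified_sequence(text),
            charge=int(row["Charge"]),
            proteins=tuple(p for p in row["Proteins"].split("/") if p),
            score=float(row["Final_Score"]),
            precursor_intensity=_opt_float(row.get("Intensity", "")),
            run_id=row["File_Name"],
            sample_type=row.get("sample_type", ""),
        )
    # maxquant-peptides: RT printed in minutes; first listed charge used
    charge = int(str(row["Charges"]).split(";")[0])
    return PSMRecord(
        scan_id=f"mq_{idx}",
        rt_seconds=60.0 * float(row["Retention time"]),
        peptide=parse_modified_sequence(row["Sequence"]),
        charge=charge,
        proteins=tuple(p for p in row["Proteins"].split(";") if p),
        score=float(row["Score"]),
        precursor_intensity=_opt_float(row["Intensity"]),
        run_id=row.get("Raw file", "run0") or "run0",
        sample_type=row.get("sample_type", ""),
    )


def _apply_pfind_mods(seq: str, mod_field: str) -> str:
    """Convert a pFind ``pos,Name;``-style modification field to UniMod text."""
    if not mod_field:
        return seq
    name_to_uid = {"Carbamidomethyl[C]": 4, "Oxidation[M]": 35, "Acetyl[ProteinN-term]": 1}
    tags: dict[int, int] = {}
    for part in mod_field.strip(";").split(";"):
        if not part:
            continue
        pos_s, name = part.split(",", 1)
        uid = name_to_uid.get(name.strip())
        if uid is None:
            raise ValueError(f"unsupported pFind modification {name!r}")
        tags[int(pos_s)] = uid
    out = []
    if 0 in tags:
        out.append(f"[UniMod:{tags[0]}]")
    for i, res in enumerate(seq, start=1):
        out.append(res)
        if i in tags:
            out.append(f"[UniMod:{tags[i]}]")
    return "".join(out)


def _opt_float(text: object) -> Optional[float]:
    s = str(text).strip()
    if not s or s.lower() == "nan":
        return None
    return float(s)


def write_psm_table(table: PSMTable, path: str | os.PathLike) -> None:
    """Write a table in the generic dialect (inverse of the generic reader)."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "scan_id": r.scan_id,
                "run_id": r.run_id,
                "rt_seconds": repr(r.rt_seconds),
                "sequence": r.peptide.to_unimod_string(),
                "charge": r.charge,
                "proteins": ";".join(r.proteins),
                "score": repr(r.score),
                "precursor_intensity": "" if r.precursor_intensity is None else repr(r.precursor_intensity),
                "sample_type": r.sample_type,
                "prev_aa": r.prev_aa or "",
                "next_aa": r.next_aa or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _is_tryptic(rec: PSMRecord) -> bool:
    """K/R-not-before-P junction rule; records without context pass."""
    if rec.prev_aa is None and rec.next_aa is None:
        return True
    seq = rec.peptide.sequence
    ok_n = True
    if rec.prev_aa is not None:
        ok_n = rec.prev_aa == "-" or (rec.prev_aa in "KR" and seq[0] != "P")
    ok_c = True
    if rec.next_aa is not None:
        ok_c = rec.next_aa == "-" or (seq[-1] in "KR" and rec.next_aa != "P")
    return ok_n and ok_c


def filter_psms(
    table: PSMTable,
    min_score: Optional[float] = None,
    allowed_charges: Optional[Iterable[int]] = None,
    require_tryptic: bool = False,
) -> FilterReport:
    """Drop records failing any active criterion; report removals per criterion."""
    charges = set(allowed_charges) if allowed_charges is not None else None
    removed = {"min_score": 0, "charge": 0, "tryptic": 0}
    kept: list[PSMRecord] = []
    for rec in table.records:
        if min_score is not None and rec.score < min_score:
            removed["min_score"] += 1
            continue
        if charges is not None and rec.charge not in charges:
            removed["charge"] += 1
            continue
        if require_tryptic and not _is_tryptic(rec):
            removed["tryptic"] += 1
            continue
        kept.append(rec)
    return FilterReport(PSMTable(kept, dict(table.gradient_seconds)), removed)


def read_spectra(path: str | os.PathLike) -> dict[str, Spectrum]:
    """Read MS2 spectra from MGF, mzML or mzXML into a scan-id -> Spectrum map.

    MGF scans key on their TITLE; mzML on the native id; mzXML on scan number.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    spectra: dict[str, Spectrum] = {}
    if ext == ".mgf":
        from pyteomics import mgf

        with mgf.MGF(path) as reader:
            for spec in reader:
                params = spec["params"]
                sid = str(params.get("title", ""))
                rt = params.get("rtinseconds", float("nan"))
                spectra[sid] = _to_spectrum(spec, sid, float(rt))
    elif ext == ".mzml":
        from pyteomics import mzml

        with mzml.MzML(path) as reader:
            for spec in reader:
                if spec.get("ms level") != 2:
                    continue
                sid = str(spec["id"])
                rt = float("nan")
                try:
                    rt = float(
                        spec["scanList"]["scan"][0]["scan start time"]
                    ) * 60.0
                except (KeyError, IndexError, TypeError):
                    pass
                spectra[sid] = _to_spectrum(spec, sid, rt)
    elif ext == ".mzxml":
        from pyteomics import mzxml

        with mzxml.MzXML(path) as reader:
            for spec in reader:
                if int(spec.get("msLevel", 0)) != 2:
                    continue
                sid = str(spec["num"])
                rt = float(spec.get("retentionTime", float("nan"))) * 60.0
                spectra[sid] = _to_spectrum(spec, sid, rt)
    else:
        raise ValueError(f"unsupported spectra format {ext!r}")
    return spectra


def _to_spectrum(spec: Mapping, sid: str, rt: float) -> Spectrum:
    peaks = [
        Peak(float(mz), float(inten))
        for mz, inten in zip(spec["m/z array"], spec["intensity array"])
        if inten > 0
    ]
    return Spectrum(peaks=peaks, rt_seconds=rt, scan_id=sid)


def attach_spectra(
    table: PSMTable, spectra: Mapping[str, Spectrum] | str | os.PathLike
) -> AttachResult:
    """Pair each PSM with its MS2 spectrum by scan id.

    ``spectra`` is either an already-read mapping or a path handed to
    :func:`read_spectra`.  Zero resolvable scans is a hard error — the PSM
    table and spectra file are not from the same runs.
    """
    if not isinstance(spectra, Mapping):
        spectra = read_spectra(spectra)
    pairs: list[tuple[PSMRecord, Spectrum]] = []
    unmatched: list[PSMRecord] = []
    for rec in table.records:
        spec = spectra.get(rec.scan_id)
        if spec is None:
            unmatched.append(rec)
        else:
            pairs.append((rec, spec))
    if table.records and not pairs:
        raise SpectraPairingError(
            "no PSM scan id matches the spectra source; wrong file pairing?"
        )
    return AttachResult(pairs, unmatched)
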