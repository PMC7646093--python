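"""Consensus spectrum construction from replicate identifications.

Each peptide precursor is typically identified many times across runs; the
library keeps one representative MS2 spectrum per precursor.  Peaks are
clustered greedily across replicates (seeded from the most intense
unclustered peak, window ±tol), and a cluster survives if it appears in at
least ``min_replicate_fraction`` of the replicates — a peak seen once in
five spectra is noise, a peak seen in four is signal.  Consensus m/z is the
intensity-weighted mean of the cluster, consensus intensity the median
(robust to a single aberrant replicate).  With fewer than three replicates
the fraction rule degenerates and all peaks are kept.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chem import (
    FragmentIon,
    Peak,
    PrecursorKey,
    Spectrum,
    annotate_fragments,
    match_peaks,
)
from .landmarks import CalibrationFit, apply_calibration
from .psm import PSMRecord

__all__ = [
    "ReplicateGroup",
    "ConsensusSpectrum",
    "group_by_precursor",
    "build_consensus",
    "quality_filter",
    "write_msp",
    "write_consensus_mgf",
]


@dataclass
class ReplicateGroup:
    key: PrecursorKey
    members: list[tuple[PSMRecord, Spectrum]]
    sample_type: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("replicate group must be non-empty")
        for rec, _ in self.members:
            if rec.key != self.key:
                raise ValueError("replicate group member has mismatched precursor key")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSpectrum:
    key: PrecursorKey
    peaks: list[Peak]
    n_replicates: int
    best_score: float
    irt: float
    proteins: tuple[str, ...]
    sample_type: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def as_spectrum(self) -> Spectrum:
        return Spectrum(peaks=list(self.peaks), precursor=self.key)


def group_by_precursor(
    pairs: Iterable[tuple[PSMRecord, Spectrum]]
) -> list[ReplicateGroup]:
    """Partition (PSM, spectrum) pairs by (modified sequence, charge)."""
    groups: dict[PrecursorKey, list[tuple[PSMRecord, Spectrum]]] = {}
    for rec, spec in pairs:
        groups.setdefault(rec.key, []).append((rec, spec))
    out = []
    for key in sorted(groups, key=str):
        members = groups[key]
        sample_types = sorted({r.sample_type for r, _ in members if r.sample_type})
        out.append(
            ReplicateGroup(key, members, sample_type=sample_types[0] if sample_types else "")
        )
    return out


def _strip_precursor_region(spec: Spectrum, precursor_mz: float, halfwidth: float) -> list[Peak]:
    return [p for p in spec.peaks if abs(p.mz - precursor_mz) > halfwidth]


def build_consensus(
    group: ReplicateGroup,
    tol: float = 0.03,
    min_replicate_fraction: float = 0.6,
    fit: Optional[CalibrationFit] = None,
    precursor_exclusion_halfwidth: float = 1.5,
) -> ConsensusSpectrum:
    """Aggregate a replicate group into one consensus spectrum.

    A single member passes through verbatim (after precursor-region
    removal).  iRT is the median of the members' calibrated RTs when a fit
    is supplied, else the median raw RT.
    """
    n = len(group)
    pmz = group.key.mz
    rts = [rec.rt_seconds for rec, _ in group.members]
    irt = statistics.median(
        [apply_calibration(rt, fit) for rt in rts] if fit is not None else rts
    )
    best_score = max(rec.score for rec, _ in group.members)
    proteins = tuple(sorted(set().union(*(set(r.proteins) for r, _ in group.members))))

    if n == 1:
        peaks = _strip_precursor_region(group.members[0][1], pmz, precursor_exclusion_halfwidth)
        return ConsensusSpectrum(
            key=group.key,
            peaks=list(peaks),
            n_replicates=1,
            best_score=best_score,
            irt=irt,
            proteins=proteins,
            sample_type=group.sample_type,
        )

    # pool peaks tagged with replicate index; order members canonically so the
    # result is invariant to input order
    ordered = sorted(
        enumerate(group.members), key=lambda kv: (kv[1][0].run_id, kv[1][0].scan_id)
    )
    pool: list[tuple[float, float, int]] = []  # (mz, intensity, replicate)
    for ridx, (_, (_, spec)) in enumerate(ordered):
        for p in _strip_precursor_region(spec, pmz, precursor_exclusion_halfwidth):
            pool.append((p.mz, p.intensity, ridx))
    # greedy clustering seeded from the most intense unclustered peak
    pool.sort(key=lambda t: (-t[1], t[0], t[2]))
    unused = list(pool)
    # fraction rule only applies at n >= 3; the 1e-9 guards ceil(0.6*5) == 3
    min_count = math.ceil(min_replicate_fraction * n - 1e-9) if n >= 3 else 1
    consensus_peaks: list[Peak] = []
    while unused:
        seed = unused[0]
        cluster = [t for t in unused if abs(t[0] - seed[0]) <= tol]
        unused = [t for t in unused if abs(t[0] - seed[0]) > tol]
        reps = {t[2] for t in cluster}
        if len(reps) < min_count:
            continue
        total_i = sum(t[1] for t in cluster)
        if total_i <= 0:
            continue
        mz = sum(t[0] * t[1] for t in cluster) / total_i
        intensity = statistics.median(t[1] for t in cluster)
        consensus_peaks.append(Peak(mz, intensity))
    return ConsensusSpectrum(
        key=group.key,
        peaks=consensus_peaks,
        n_replicates=n,
        best_score=best_score,
        irt=irt,
        proteins=proteins,
        sample_type=group.sample_type,
    )


def quality_filter(
    consensus_list: Sequence[ConsensusSpectrum],
    min_fragments_annotated: int = 4,
    min_replicates: int = 1,
    tol: float = 0.03,
    max_fragment_charge: int = 2,
) -> tuple[list[ConsensusSpectrum], dict[str, int]]:
    """Drop low-quality consensus entries; return survivors and removal counts."""
    kept: list[ConsensusSpectrum] = []
    removed = {"few_fragments": 0, "few_replicates": 0}
    for cs in consensus_list:
        if cs.n_replicates < min_replicates:
            removed["few_replicates"] += 1
            continue
        if min_fragments_annotated > 0:
            ions = annotate_fragments(cs.key.peptide, max_fragment_charge)
            n_annotated = len(match_peaks(cs.as_spectrum(), ions, tol))
            if n_annotated < min_fragments_annotated:
                removed["few_fragments"] += 1
                continue
        kept.append(cs)
    return kept, removed


def write_msp(consensus_list: Sequence[ConsensusSpectrum], path) -> None:
    """Write consensus spectra as MSP-style text for inspection."""
    with open(path, "w") as fh:
        for cs in consensus_list:
            fh.write(f"Name: {cs.key.peptide.to_unimod_string()}/{cs.key.charge}\n")
            fh.write(f"PrecursorMZ: {cs.key.mz:.4f}\n")
            fh.write(
                f"Comment: iRT={cs.irt:.3f} Nreps={cs.n_replicates} "
                f"Protein={';'.join(cs.proteins)}\n"
            )
            fh.write(f"Num peaks: {len(cs.peaks)}\n")
            for p in cs.peaks:
                fh.write(f"{p.mz:.4f}\t{p.intensity:.1f}\n")
            fh.write("\n")


def write_consensus_mgf(consensus_list: Sequence[ConsensusSpectrum], path) -> None:
    """Write consensus spectra as MGF."""
    with open(path, "w") as fh:
        for cs in consensus_list:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={cs.key.peptide.to_unimod_string()}/{cs.key.charge}\n")
            fh.write(f"PEPMASS={cs.key.mz:.4f}\n")
            fh.write(f"CHARGE={cs.key.charge}+\n")
            for p in cs.peaks:
                fh.write(f"{p.mz:.4f} {p.intensity:.1f}\n")
            fh.write("END IONS\n")
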