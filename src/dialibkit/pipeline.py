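"""End-to-end library build: import -> filter -> calibrate -> consensus ->
assays -> decoys -> serialize, with a QC report of per-stage counts."""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import __version__
from .assays import (
    AssayRejected,
    Library,
    TransitionConfig,
    assemble_library,
    select_transitions,
)
from .chem import Spectrum
from .consensus import build_consensus, group_by_precursor, quality_filter
from .inference import library_stats
from .landmarks import (
    CalibrationFit,
    CiRTConfig,
    LandmarkSet,
    apply_calibration,
    assign_reference_irt,
    fit_irt_map,
    select_cirt,
)
from .psm import PSMTable, attach_spectra, filter_psms

__all__ = ["BuildConfig", "BuildResult", "run_build", "calibrate_runs"]


@dataclass
class BuildConfig:
    cirt: CiRTConfig = field(default_factory=CiRTConfig)
    transitions: TransitionConfig = field(default_factory=TransitionConfig)
    consensus_tol: float = 0.03
    min_replicate_fraction: float = 0.6
    min_fragments_annotated: int = 3
    min_replicates: int = 1
    min_score: Optional[float] = None
    allowed_charges: Optional[tuple[int, ...]] = None
    require_tryptic: bool = False
    decoy_method: str = "pseudo-reverse"
    seed: int = 0


@dataclass
class BuildResult:
    library: Library
    stats: "object"
    qc: dict
    fits: dict[str, CalibrationFit]
    landmarks: Optional[LandmarkSet]


def calibrate_runs(
    table: PSMTable, landmarks: LandmarkSet
) -> dict[str, CalibrationFit]:
    """Fit one RT -> iRT map per run from landmark observations.

    Landmark reference iRTs must be assigned.  A run without at least three
    observed landmarks raises through :func:`fit_irt_map`.
    """
    ref = {
        lm.key: lm.reference_irt
        for lm in landmarks.landmarks
        if lm.reference_irt is not None
    }
    if len(ref) < 3:
        raise ValueError("landmark set has fewer than 3 reference iRT values")
    by_run: dict[str, dict] = {}
    for rec in table.records:
        irt = ref.get(rec.key)
        if irt is None:
            continue
        by_run.setdefault(rec.run_id, {}).setdefault(rec.key, []).append(rec.rt_seconds)
    fits = {}
    for run_id in sorted(table.gradient_seconds):
        obs = by_run.get(run_id, {})
        pairs = [(statistics.median(rts), ref[key]) for key, rts in obs.items()]
        keys = list(obs)
        fits[run_id] = fit_irt_map(pairs, keys=keys)
    return fits


def run_build(
    table: PSMTable,
    spectra: Mapping[str, Spectrum],
    config: BuildConfig = BuildConfig(),
    landmarks: Optional[LandmarkSet] = None,
    sample_type: str = "",
) -> BuildResult:
    """Build a decoy-appended library from a PSM table and its spectra.

    If ``landmarks`` (e.g. a SiRT set with vendor iRT values) is given it
    anchors the calibration; otherwise CiRT landmarks are discovered from
    the table and min-max scaled onto [0, 100].
    """
    qc: dict = {"stages": {}, "tool_version": __version__}
    qc["stages"]["input_psms"] = len(table)

    report = filter_psms(
        table,
        min_score=config.min_score,
        allowed_charges=config.allowed_charges,
        require_tryptic=config.require_tryptic,
    )
    table = report.table
    qc["stages"]["filtered_psms"] = len(table)
    qc["stages"]["filter_removed"] = report.removed

    if landmarks is None:
        landmarks = select_cirt(table, config=config.cirt, provenance=sample_type)
        landmarks = assign_reference_irt(landmarks)
        qc["stages"]["cirt_landmarks"] = len(landmarks)
        qc["landmark_warnings"] = list(landmarks.warnings)
    fits = calibrate_runs(table, landmarks)
    qc["calibration"] = {
        run: {"slope": f.slope, "intercept": f.intercept, "r_squared": f.r_squared,
              "n_points": f.n_points_used, "n_outliers": len(f.outlier_keys)}
        for run, f in fits.items()
    }

    attach = attach_spectra(table, spectra)
    qc["stages"]["psms_with_spectra"] = len(attach.pairs)
    qc["stages"]["psms_without_spectra"] = len(attach.unmatched)

    groups = group_by_precursor(attach.pairs)
    qc["stages"]["replicate_groups"] = len(groups)
    consensus = []
    for grp in groups:
        # calibrate each member with its own run's fit; consensus iRT is the
        # median over members
        irts = [
            apply_calibration(rec.rt_seconds, fits[rec.run_id])
            for rec, _ in grp.members
        ]
        cs = build_consensus(
            grp,
            tol=config.consensus_tol,
            min_replicate_fraction=config.min_replicate_fraction,
        )
        cs.irt = statistics.median(irts)
        if sample_type:
            cs.sample_type = sample_type
        consensus.append(cs)
    kept, removed = quality_filter(
        consensus,
        min_fragments_annotated=config.min_fragments_annotated,
        min_replicates=config.min_replicates,
        tol=config.consensus_tol,
    )
    qc["stages"]["consensus_spectra"] = len(consensus)
    qc["stages"]["consensus_removed"] = removed

    targets = []
    rejected = 0
    for cs in kept:
        try:
            targets.append(select_transitions(cs, config.transitions))
        except AssayRejected:
            rejected += 1
    qc["stages"]["assays"] = len(targets)
    qc["stages"]["assays_rejected"] = rejected
    if not targets:
        raise RuntimeError("assay selection produced no target entries")

    library = assemble_library(
        targets,
        decoy_method=config.decoy_method,
        seed=config.seed,
        metadata={
            "sample_type": sample_type,
            "consensus_tol": config.consensus_tol,
            "min_replicate_fraction": config.min_replicate_fraction,
            "top_n": config.transitions.top_n,
        },
    )
    qc["stages"]["library_entries"] = len(library)
    stats = library_stats(library)
    qc["library_stats"] = stats.__dict__
    return BuildResult(library=library, stats=stats, qc=qc, fits=fits, landmarks=landmarks)
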