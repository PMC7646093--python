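"""Endogenous retention-time landmark selection and RT -> iRT calibration.

Two calibration strategies are supported.  With synthetic spiked-in iRT
standards (SiRT), the user supplies the kit's reference iRT values and the
fit maps observed RT onto that scale.  Without spike-ins, common internal RT
(CiRT) landmarks are discovered from the data itself: abundant, unmodified,
proteotypic peptides at charge 2-3, spread uniformly over the gradient by
taking one peptide per equal-width RT bin (20 bins by default, hence 20
landmarks per sample type).  The RT -> iRT map is affine, fit by least
squares with iterated MAD-based outlier rejection.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .chem import PrecursorKey
from .psm import PSMTable

__all__ = [
    "CiRTConfig",
    "LandmarkPeptide",
    "LandmarkSet",
    "CalibrationFit",
    "EmptyLandmarkError",
    "InsufficientLandmarksError",
    "DegenerateFitError",
    "select_cirt",
    "assign_reference_irt",
    "fit_irt_map",
    "apply_calibration",
    "invert_calibration",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
]


class EmptyLandmarkError(RuntimeError):
    """No candidate peptide survived the landmark criteria."""


class InsufficientLandmarksError(RuntimeError):
    """Fewer than three usable calibration points."""


class DegenerateFitError(RuntimeError):
    """Calibration points have no RT variance."""


@dataclass(frozen=True)
class CiRTConfig:
    """Selection criteria for common internal RT landmark peptides."""

    n_bins: int = 20
    intensity_quantile: float = 0.75
    allowed_charges: frozenset[int] = frozenset({2, 3})
    require_unmodified: bool = True
    require_proteotypic: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.intensity_quantile < 1:
            raise ValueError("intensity_quantile must be in (0, 1)")


@dataclass(frozen=True)
class LandmarkPeptide:
    key: PrecursorKey
    reference_irt: Optional[float] = None
    source: str = "CiRT"
    median_rt_seconds: float = float("nan")
    intensity: float = float("nan")


@dataclass
class LandmarkSet:
    landmarks: list[LandmarkPeptide]
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [lm.key for lm in self.landmarks]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate landmark keys")

    def __len__(self) -> int:
        return len(self.landmarks)


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    n_points_used: int
    outlier_keys: tuple = ()

    def __post_init__(self) -> None:
        if self.n_points_used < 3:
            raise ValueError("a calibration fit needs >= 3 points")
        if self.slope == 0:
            raise ValueError("degenerate fit: zero slope")


def _aggregate_precursors(table: PSMTable) -> list[dict]:
    """Collapse PSMs to precursors: RT = median, intensity = max, score = max."""
    groups: dict[PrecursorKey, list] = {}
    for rec in table.records:
        groups.setdefault(rec.key, []).append(rec)
    out = []
    for key, recs in groups.items():
        intens = [r.precursor_intensity for r in recs if r.precursor_intensity is not None]
        out.append(
            {
                "key": key,
                "rt": statistics.median(r.rt_seconds for r in recs),
                "intensity": max(intens) if intens else None,
                "score": max(r.score for r in recs),
                "proteins": set().union(*(set(r.proteins) for r in recs)),
            }
        )
    return out


def select_cirt(
    table: PSMTable,
    peptide_proteotypicity: Optional[Mapping[str, bool]] = None,
    config: CiRTConfig = CiRTConfig(),
    provenance: str = "",
) -> LandmarkSet:
    """Discover CiRT landmark peptides from a quantified PSM table.

    Candidates must be proteotypic, unmodified, at an allowed charge and have
    precursor intensity strictly above the configured quantile of all
    quantified precursors.  The observed candidate RT span is cut into
    ``n_bins`` equal-width bins and the most intense candidate is taken from
    each non-empty bin (ties: higher score, then lexicographically smaller
    sequence).  Reference iRT values are left unset.
    """
    precursors = _aggregate_precursors(table)
    quantified = [p for p in precursors if p["intensity"] is not None]
    if not quantified:
        raise EmptyLandmarkError("no precursor carries an intensity")
    cutoff = float(
        np.quantile([p["intensity"] for p in quantified], config.intensity_quantile)
    )

    def proteotypic(p: dict) -> bool:
        seq = p["key"].peptide.sequence
        if peptide_proteotypicity is not None:
            return bool(peptide_proteotypicity.get(seq, False))
        return len(p["proteins"]) == 1

    candidates = []
    for p in quantified:
        if p["key"].charge not in config.allowed_charges:
            continue
        if config.require_unmodified and p["key"].peptide.is_modified:
            continue
        if config.require_proteotypic and not proteotypic(p):
            continue
        if p["intensity"] <= cutoff:
            continue
        candidates.append(p)
    if not candidates:
        raise EmptyLandmarkError("no candidate passed the CiRT criteria")

    rts = [p["rt"] for p in candidates]
    lo, hi = min(rts), max(rts)
    width = (hi - lo) / config.n_bins if hi > lo else 1.0
    bins: dict[int, list] = {}
    for p in candidates:
        b = int((p["rt"] - lo) / width) if hi > lo else 0
        b = min(b, config.n_bins - 1)
        bins.setdefault(b, []).append(p)

    landmarks = []
    for b in sorted(bins):
        best = max(
            bins[b],
            key=lambda p: (p["intensity"], p["score"], _neg_lex(p["key"].peptide.sequence)),
        )
        landmarks.append(
            LandmarkPeptide(
                key=best["key"],
                source="CiRT",
                median_rt_seconds=best["rt"],
                intensity=best["intensity"],
            )
        )
    warnings = []
    n_empty = config.n_bins - len(bins)
    if n_empty > 0.25 * config.n_bins:
        warnings.append(
            f"{n_empty}/{config.n_bins} gradient bins had no candidate peptide"
        )
    return LandmarkSet(landmarks, provenance=provenance, warnings=warnings)


class _neg_lex(str):
    """Inverts lexicographic order so max() picks the smallest sequence."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def assign_reference_irt(
    landmark_set: LandmarkSet,
    anchor: Optional["CalibrationFit"] = None,
    reference_rts: Optional[Mapping[PrecursorKey, float]] = None,
) -> LandmarkSet:
    """Give each landmark a reference iRT value.

    With a SiRT-anchored calibration ``anchor``, each landmark's RT (from
    ``reference_rts`` if given, else its own median RT) is pushed through the
    fit.  Without an anchor, landmark RTs are min-max scaled onto [0, 100],
    the conventional iRT span.  Landmarks missing from ``reference_rts`` are
    dropped with a warning; fewer than 3 survivors is an error.
    """
    survivors: list[LandmarkPeptide] = []
    warnings = list(landmark_set.warnings)
    rts: list[float] = []
    for lm in landmark_set.landmarks:
        if reference_rts is not None:
            rt = reference_rts.get(lm.key)
            if rt is None:
                warnings.append(f"landmark {lm.key} absent from reference run; dropped")
                continue
        else:
            rt = lm.median_rt_seconds
        survivors.append(lm)
        rts.append(rt)
    if len(survivors) < 3:
        raise InsufficientLandmarksError(
            f"only {len(survivors)} landmarks usable for reference iRT assignment"
        )
    if anchor is not None:
        irts = [apply_calibration(rt, anchor) for rt in rts]
    else:
        lo, hi = min(rts), max(rts)
        if hi == lo:
            raise DegenerateFitError("landmark RTs have zero spread")
        irts = [100.0 * (rt - lo) / (hi - lo) for rt in rts]
    out = [
        LandmarkPeptide(
            key=lm.key,
            reference_irt=irt,
            source=lm.source,
            median_rt_seconds=lm.median_rt_seconds,
            intensity=lm.intensity,
        )
        for lm, irt in zip(survivors, irts)
    ]
    return LandmarkSet(out, provenance=landmark_set.provenance, warnings=warnings)


def fit_irt_map(
    observed: Sequence[tuple[float, float]],
    keys: Optional[Sequence] = None,
    mad_multiplier: float = 3.0,
    max_rounds: int = 5,
) -> CalibrationFit:
    """Robust affine fit of iRT on observed RT.

    Ordinary least squares, then iterated outlier rejection: points whose
    absolute residual exceeds ``mad_multiplier`` x the median absolute
    deviation of residuals are dropped and the line refit, to a fixpoint or
    ``max_rounds`` rounds.  r^2 is reported on the surviving points.
    """
    if len(observed) < 3:
        raise InsufficientLandmarksError(f"need >= 3 calibration pairs, got {len(observed)}")
    x = np.asarray([p[0] for p in observed], dtype=float)
    y = np.asarray([p[1] for p in observed], dtype=float)
    if keys is None:
        keys = list(range(len(observed)))
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero RT variance among calibration points")
    mask = np.ones(len(x), dtype=bool)
    slope = intercept = 0.0
    for _ in range(max_rounds):
        if mask.sum() < 3:
            raise InsufficientLandmarksError("fewer than 3 points survive outlier rejection")
        if np.ptp(x[mask]) == 0:
            raise DegenerateFitError("zero RT variance among surviving points")
        slope, intercept = np.polyfit(x[mask], y[mask], 1)
        resid = y - (slope * x + intercept)
        center = float(np.median(resid[mask]))
        # 1.4826 x MAD estimates sigma consistently under Gaussian noise, so
        # the cut sits at mad_multiplier robust sigmas and does not cascade
        sigma = 1.4826 * float(np.median(np.abs(resid[mask] - center)))
        if sigma == 0:
            break
        new_mask = np.abs(resid - center) <= mad_multiplier * sigma
        new_mask &= mask  # rejection is monotone: once out, stays out
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
    if mask.sum() < 3:
        raise InsufficientLandmarksError("fewer than 3 points survive outlier rejection")
    yv = y[mask]
    fitted = slope * x[mask] + intercept
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    outliers = tuple(k for k, m in zip(keys, mask) if not m)
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points_used=int(mask.sum()),
        outlier_keys=outliers,
    )


def apply_calibration(rt_seconds: float, fit: CalibrationFit) -> float:
    """Map an observed RT (seconds) onto the iRT scale."""
    return fit.slope * rt_seconds + fit.intercept


def invert_calibration(irt: float, fit: CalibrationFit) -> float:
    """Map an iRT value back to predicted RT (seconds)."""
    return (irt - fit.intercept) / fit.slope


def write_landmarks_tsv(landmark_set: LandmarkSet, path) -> None:
    import pandas as pd

    rows = [
        {
            "sequence": lm.key.peptide.to_unimod_string(),
            "charge": lm.key.charge,
            "reference_irt": "" if lm.reference_irt is None else repr(lm.reference_irt),
            "source": lm.source,
        }
        for lm in landmark_set.landmarks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_landmarks_tsv(path) -> LandmarkSet:
    import pandas as pd

    from .chem import parse_modified_sequence

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence", "charge", "reference_irt", "source"):
        if col not in df.columns:
            raise ValueError(f"landmark TSV missing column {col!r}")
    landmarks = [
        LandmarkPeptide(
            key=PrecursorKey(parse_modified_sequence(r["sequence"]), int(r["charge"])),
            reference_irt=float(r["reference_irt"]) if r["reference_irt"] else None,
            source=r["source"] or "SiRT",
        )
        for _, r in df.iterrows()
    ]
    return LandmarkSet(landmarks)
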