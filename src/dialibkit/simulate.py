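"""Seeded synthetic proteomes, PSM runs and spectra with known ground truth.

Emulates the DDA inputs of a library build so every stage is testable
without raw data: random protein sequences digested in silico (tryptic,
cleave after K/R unless followed by P), peptides with hidden iRT values on
the conventional [0, 100] scale, per-run affine iRT -> RT transforms with
Gaussian jitter, log-normal precursor intensities (the heavy-tailed
abundance the third-quartile intensity filter presumes), charge states
drawn 1:2:3:4 = 0.05:0.60:0.30:0.05, and MS2 spectra made of the peptide's
true b/y fragment profile plus Poisson-count uniform noise peaks.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (
    ModifiedPeptide,
    Peak,
    PrecursorKey,
    Spectrum,
    annotate_fragments,
)
from .psm import PSMRecord, PSMTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "digest",
    "generate_proteome",
    "simulate_runs",
    "write_fasta",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 20
    protein_length: tuple[int, int] = (120, 400)
    missed_cleavages: int = 0
    min_peptide_length: int = 7
    max_peptide_length: int = 30
    gradient_seconds: float = 3600.0
    rt_noise_sd: float = 5.0
    intensity_log_mean: float = 12.0
    intensity_log_sd: float = 1.5
    charge_probs: tuple[float, ...] = (0.05, 0.60, 0.30, 0.05)  # z = 1..4
    n_fragment_peaks: tuple[int, int] = (8, 14)
    noise_peak_rate: float = 5.0
    fragment_mz_range: tuple[float, float] = (200.0, 1500.0)


@dataclass
class GroundTruth:
    config: SimulationConfig
    seed: int
    proteome: dict[str, str]
    peptide_to_proteins: dict[str, tuple[str, ...]]
    hidden_irt: dict[str, float]
    run_transforms: dict[str, tuple[float, float]]  # run_id -> (slope s/iRT, intercept s)
    fragment_profiles: dict[PrecursorKey, list[tuple[str, int, int, float, float]]]
    # (series, ordinal, charge, mz, intensity) of true fragments per precursor


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    min_length: int = 1,
    max_length: int = 10_000,
    semi_tryptic_fraction: float = 0.0,
    rng: Optional[random.Random] = None,
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R unless the next residue is P.

    ``missed_cleavages`` adds concatenations of up to that many adjacent
    fragments; ``semi_tryptic_fraction`` randomly truncates that fraction of
    peptides at one terminus (requires ``rng``).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    cuts = [0]
    for i, res in enumerate(sequence[:-1]):
        if res in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    base = [sequence[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
    peptides = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(base) - mc):
            peptides.append("".join(base[i : i + mc + 1]))
    if semi_tryptic_fraction > 0:
        if rng is None:
            raise ValueError("semi_tryptic_fraction needs an rng")
        extra = []
        for pep in peptides:
            if len(pep) > 3 and rng.random() < semi_tryptic_fraction:
                k = rng.randint(1, len(pep) - 2)
                extra.append(pep[k:] if rng.random() < 0.5 else pep[:-k])
        peptides += extra
    return [p for p in peptides if min_length <= len(p) <= max_length]


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 400),
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> tuple[dict[str, str], dict[str, tuple[str, ...]]]:
    """Random proteome plus its tryptic peptide -> protein map.

    Accessions follow Swiss-Prot header style (``sp|Pxxxxx|GENEx_HUMAN``) so
    canonicality flags downstream behave as with a real database.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    cfg = config or SimulationConfig(n_proteins=n_proteins, protein_length=length_range)
    rng = random.Random(seed)
    base = rng.randrange(900_000)  # seed-specific accession block
    proteome: dict[str, str] = {}
    for i in range(n_proteins):
        length = rng.randint(*length_range)
        seq = "".join(rng.choice(_AA) for _ in range(length))
        acc = f"sp|P{base + i:06d}|GENE{i}_HUMAN"
        proteome[acc] = seq
    pep_map: dict[str, set[str]] = {}
    for acc, seq in proteome.items():
        for pep in digest(
            seq,
            missed_cleavages=cfg.missed_cleavages,
            min_length=cfg.min_peptide_length,
            max_length=cfg.max_peptide_length,
        ):
            pep_map.setdefault(pep, set()).add(acc)
    return proteome, {p: tuple(sorted(a)) for p, a in pep_map.items()}


def write_fasta(proteome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _true_fragments(
    key: PrecursorKey, cfg: SimulationConfig, rng: random.Random
) -> list[tuple[str, int, int, float, float]]:
    ions = [
        ion
        for ion in annotate_fragments(key.peptide, 2)
        if cfg.fragment_mz_range[0] <= ion.mz <= cfg.fragment_mz_range[1]
    ]
    if not ions:
        ions = annotate_fragments(key.peptide, 2)
    n = min(len(ions), rng.randint(*cfg.n_fragment_peaks))
    chosen = rng.sample(ions, n)
    return [
        (ion.series, ion.ordinal, ion.charge, ion.mz, rng.lognormvariate(math.log(1000.0), 0.8))
        for ion in chosen
    ]


def simulate_runs(
    n_runs: int = 3,
    n_psms: int = 1000,
    seed: int = 0,
    config: SimulationConfig = SimulationConfig(),
    proteome: Optional[dict[str, str]] = None,
    peptide_map: Optional[dict[str, tuple[str, ...]]] = None,
    sample_type: str = "synthetic",
) -> tuple[PSMTable, dict[str, Spectrum], GroundTruth]:
    """Simulate DDA runs: a PSM table, MS2 spectra keyed by scan id, and the
    generating ground truth.

    Peptides are sampled (with replacement across runs, so precursors repeat
    and consensus building has replicates) with hidden iRT uniform on
    [0, 100]; each run maps iRT to RT through its own affine transform
    spanning roughly the middle 80% of the gradient, plus Gaussian noise of
    ``config.rt_noise_sd`` seconds.
    """
    rng = random.Random(seed)
    if proteome is None or peptide_map is None:
        proteome, peptide_map = generate_proteome(
            config.n_proteins, config.protein_length, seed=rng.randrange(2**31), config=config
        )
    peptides = sorted(peptide_map)
    if not peptides:
        raise ValueError("proteome digest yielded no peptides")
    hidden_irt = {p: rng.uniform(0.0, 100.0) for p in peptides}
    # fixed charge per peptide: one precursor per peptide keeps truth simple
    charges = {
        p: rng.choices(range(1, len(config.charge_probs) + 1), config.charge_probs)[0]
        for p in peptides
    }
    base_intensity = {
        p: rng.lognormvariate(config.intensity_log_mean, config.intensity_log_sd)
        for p in peptides
    }
    run_transforms: dict[str, tuple[float, float]] = {}
    fragment_profiles: dict[PrecursorKey, list] = {}
    records: list[PSMRecord] = []
    spectra: dict[str, Spectrum] = {}
    scan_no = 0
    for r in range(n_runs):
        run_id = f"run{r}"
        slope = config.gradient_seconds * rng.uniform(0.0078, 0.0086)
        intercept = config.gradient_seconds * rng.uniform(0.05, 0.12)
        run_transforms[run_id] = (slope, intercept)
        for _ in range(n_psms):
            pep = rng.choice(peptides)
            key = PrecursorKey(ModifiedPeptide(pep), charges[pep])
            if key not in fragment_profiles:
                fragment_profiles[key] = _true_fragments(key, config, rng)
            rt = slope * hidden_irt[pep] + intercept + rng.gauss(0.0, config.rt_noise_sd)
            rt = min(max(rt, 0.0), config.gradient_seconds)
            scan_no += 1
            scan_id = f"scan_{scan_no}"
            peaks = [
                Peak(mz, inten * rng.uniform(0.7, 1.3))
                for (_, _, _, mz, inten) in fragment_profiles[key]
            ]
            n_noise = np.random.default_rng(seed * 1_000_003 + scan_no).poisson(
                config.noise_peak_rate
            )
            for _ in range(int(n_noise)):
                peaks.append(
                    Peak(
                        rng.uniform(*config.fragment_mz_range),
                        rng.lognormvariate(math.log(50.0), 0.5),
                    )
                )
            spectra[scan_id] = Spectrum(
                peaks=_merge_close(peaks), rt_seconds=rt, scan_id=scan_id
            )
            records.append(
                PSMRecord(
                    scan_id=scan_id,
                    rt_seconds=rt,
                    peptide=key.peptide,
                    charge=key.charge,
                    proteins=peptide_map[pep],
                    score=rng.uniform(20.0, 100.0),
                    precursor_intensity=base_intensity[pep] * rng.uniform(0.6, 1.4),
                    run_id=run_id,
                    sample_type=sample_type,
                )
            )
    table = PSMTable(records, {r: config.gradient_seconds for r in run_transforms})
    truth = GroundTruth(
        config=config,
        seed=seed,
        proteome=proteome,
        peptide_to_proteins=peptide_map,
        hidden_irt=hidden_irt,
        run_transforms=run_transforms,
        fragment_profiles=fragment_profiles,
    )
    return table, spectra, truth


def _merge_close(peaks: list[Peak], tol: float = 1e-4) -> list[Peak]:
    """Merge peaks closer than tol so spectra keep strictly increasing m/z."""
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda q: q.mz):
        if out and p.mz - out[-1].mz < tol:
            out[-1] = Peak(out[-1].mz, out[-1].intensity + p.intensity)
        else:
            out.append(p)
    return out


def dense_cirt_run(
    n_precursors: int = 1000,
    gradient_seconds: float = 3600.0,
    seed: int = 0,
) -> PSMTable:
    """One synthetic run dense enough that no CiRT gradient bin is empty.

    ``n_precursors`` distinct unmodified, proteotypic peptides uniformly
    covering the gradient, log-normal intensities, charges predominantly
    2-3 — the conditions under which bin-based landmark selection returns a
    full complement of one peptide per bin.
    """
    rng = random.Random(seed)
    records = []
    seen: set[str] = set()
    i = 0
    while len(seen) < n_precursors:
        length = rng.randint(8, 16)
        pep = "".join(rng.choice("ACDEFGHILMNQSTVWY") for _ in range(length - 1)) + rng.choice("KR")
        if pep in seen:
            continue
        seen.add(pep)
        rt = (len(seen) - 0.5) / n_precursors * gradient_seconds * rng.uniform(0.97, 1.03)
        rt = min(max(rt, 0.0), gradient_seconds)
        records.append(
            PSMRecord(
                scan_id=f"scan_{i}",
                rt_seconds=rt,
                peptide=ModifiedPeptide(pep),
                charge=rng.choices((2, 3), (0.7, 0.3))[0],
                proteins=(f"sp|P{20000 + len(seen):05d}|G{len(seen)}_HUMAN",),
                score=rng.uniform(20.0, 100.0),
                precursor_intensity=rng.lognormvariate(12.0, 1.5),
                run_id="dense_run",
                sample_type="synthetic",
            )
        )
        i += 1
    return PSMTable(records, {"dense_run": gradient_seconds})
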