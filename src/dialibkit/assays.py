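"""Transition-assay generation: top-N product-ion selection and decoys.

A consensus spectrum becomes an assay by annotating its peaks with b/y
fragment ions, discarding products outside the usable m/z range or too close
to the precursor (they would co-extract with it in DIA), and keeping the
``top_n`` most intense annotated products — six by default, the standard
depth for DIA assay libraries.  Decoys are pseudo-reversed copies (reverse
all residues but the C-terminal one, so tryptic y1 behaviour and precursor
mass are preserved) with product m/z recomputed for the same ion labels;
palindromic prefixes fall back to a seeded shuffle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .chem import (
    FragmentIon,
    Modification,
    ModifiedPeptide,
    PrecursorKey,
    annotate_fragments,
    match_peaks,
    precursor_mz,
)
from .consensus import ConsensusSpectrum

__all__ = [
    "TransitionConfig",
    "Transition",
    "AssayEntry",
    "Library",
    "AssayRejected",
    "DecoyFailure",
    "select_transitions",
    "generate_decoy",
    "assemble_library",
]


class AssayRejected(RuntimeError):
    """No usable product ion; the consensus cannot become an assay."""


class DecoyFailure(RuntimeError):
    """No decoy sequence distinct from the target could be produced."""


@dataclass(frozen=True)
class TransitionConfig:
    top_n: int = 6
    fragment_mz_min: float = 300.0
    fragment_mz_max: float = 1800.0
    precursor_exclusion_halfwidth: float = 9.0
    allowed_series: frozenset[str] = frozenset({"b", "y"})
    allowed_fragment_charges: frozenset[int] = frozenset({1, 2})
    match_tol: float = 0.03

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.fragment_mz_min >= self.fragment_mz_max:
            raise ValueError("fragment_mz_min must be < fragment_mz_max")


@dataclass(frozen=True)
class Transition:
    precursor_mz: float
    product_mz: float
    library_intensity: float
    annotation: FragmentIon
    irt: float
    is_decoy: bool
    transition_name: str
    peptide: ModifiedPeptide
    charge: int
    proteins: tuple[str, ...]


@dataclass
class AssayEntry:
    key: PrecursorKey
    transitions: list[Transition]
    irt: float
    proteins: tuple[str, ...]
    is_decoy: bool = False
    n_replicates: int = 1
    sample_type: str = ""
    best_score: float = float("nan")
    target_group_id: str = ""  # for decoys: the group id of their target

    def __post_init__(self) -> None:
        if not self.transitions:
            raise ValueError("assay entry must have at least one transition")
        for t in self.transitions:
            if t.is_decoy != self.is_decoy:
                raise ValueError("transition decoy flag mismatch")

    @property
    def group_id(self) -> str:
        prefix = "DECOY_" if self.is_decoy else ""
        return f"{prefix}{self.key.peptide.to_unimod_string()}/{self.key.charge}"

    def __len__(self) -> int:
        return len(self.transitions)


@dataclass
class Library:
    entries: list[AssayEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.group_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate assay group ids in library")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> list[AssayEntry]:
        return [e for e in self.entries if not e.is_decoy]

    @property
    def decoys(self) -> list[AssayEntry]:
        return [e for e in self.entries if e.is_decoy]


def select_transitions(
    consensus: ConsensusSpectrum, config: TransitionConfig = TransitionConfig()
) -> AssayEntry:
    """Pick the top-N annotated product ions of a consensus spectrum.

    Candidates are consensus peaks matched (±match_tol) to allowed b/y ions,
    inside [fragment_mz_min, fragment_mz_max] and outside the precursor
    exclusion window.  Ranking is by library intensity descending, ties by
    lower product m/z.  Raises :class:`AssayRejected` if nothing survives.
    """
    key = consensus.key
    pmz = key.mz
    ions = [
        ion
        for ion in annotate_fragments(key.peptide, max(config.allowed_fragment_charges))
        if ion.series in config.allowed_series
        and ion.charge in config.allowed_fragment_charges
    ]
    matched = match_peaks(consensus.as_spectrum(), ions, config.match_tol)
    candidates = []
    for ion, peak in matched.items():
        if not config.fragment_mz_min <= peak.mz <= config.fragment_mz_max:
            continue
        if abs(peak.mz - pmz) <= config.precursor_exclusion_halfwidth:
            continue
        candidates.append((ion, peak))
    if not candidates:
        raise AssayRejected(f"no usable product ion for {key}")
    candidates.sort(key=lambda ip: (-ip[1].intensity, ip[1].mz))
    chosen = candidates[: config.top_n]
    gid = f"{key.peptide.to_unimod_string()}/{key.charge}"
    transitions = [
        Transition(
            precursor_mz=pmz,
            product_mz=peak.mz,
            library_intensity=peak.intensity,
            annotation=ion,
            irt=consensus.irt,
            is_decoy=False,
            transition_name=f"{i}_{gid}_{ion.label}",
            peptide=key.peptide,
            charge=key.charge,
            proteins=consensus.proteins,
        )
        for i, (ion, peak) in enumerate(chosen)
    ]
    return AssayEntry(
        key=key,
        transitions=transitions,
        irt=consensus.irt,
        proteins=consensus.proteins,
        is_decoy=False,
        n_replicates=consensus.n_replicates,
        sample_type=consensus.sample_type,
        best_score=consensus.best_score,
    )


def _permute_peptide(peptide: ModifiedPeptide, order: Sequence[int]) -> ModifiedPeptide:
    """Reorder residues 1..n by ``order`` (0-based old indices); mods travel."""
    seq = "".join(peptide.sequence[i] for i in order)
    new_pos = {old + 1: new + 1 for new, old in enumerate(order)}
    mods = tuple(
        Modification(0 if m.position == 0 else new_pos[m.position], m.unimod_id, m.mass_delta)
        for m in peptide.mods
    )
    return ModifiedPeptide(seq, mods)


def pseudo_reverse(peptide: ModifiedPeptide) -> ModifiedPeptide:
    """Reverse residues 1..n-1, keep the C-terminal residue in place."""
    n = len(peptide)
    order = list(range(n - 2, -1, -1)) + [n - 1]
    return _permute_peptide(peptide, order)


def generate_decoy(
    entry: AssayEntry,
    method: str = "pseudo-reverse",
    seed: Optional[int] = None,
    max_tries: int = 10,
) -> AssayEntry:
    """Build the decoy counterpart of a target assay.

    The decoy peptide keeps the target's amino-acid composition (precursor
    m/z unchanged) while scrambling internal fragment masses.  Product m/z
    is recomputed for the same (series, ordinal, charge) annotations;
    library intensities and iRT are kept.
    """
    if entry.is_decoy:
        raise ValueError("cannot decoy a decoy entry")
    if method not in ("pseudo-reverse", "shuffle"):
        raise ValueError(f"unknown decoy method {method!r}")
    peptide = entry.key.peptide
    n = len(peptide)
    rng = random.Random(seed)
    decoy_peptide: Optional[ModifiedPeptide] = None
    if method == "pseudo-reverse":
        cand = pseudo_reverse(peptide)
        if cand.sequence != peptide.sequence:
            decoy_peptide = cand
    if decoy_peptide is None:  # shuffle requested, or palindromic fallback
        for _ in range(max_tries):
            order = list(range(n - 1))
            rng.shuffle(order)
            cand = _permute_peptide(peptide, order + [n - 1])
            if cand.sequence != peptide.sequence:
                decoy_peptide = cand
                break
    if decoy_peptide is None:
        raise DecoyFailure(f"no distinct decoy sequence for {peptide.sequence}")

    decoy_key = PrecursorKey(decoy_peptide, entry.key.charge)
    ion_mz = {
        (ion.series, ion.ordinal, ion.charge): ion.mz
        for ion in annotate_fragments(decoy_peptide, max(t.annotation.charge for t in entry.transitions))
    }
    gid = f"DECOY_{decoy_key.peptide.to_unimod_string()}/{decoy_key.charge}"
    transitions = []
    for i, t in enumerate(entry.transitions):
        ann = t.annotation
        new_mz = ion_mz[(ann.series, ann.ordinal, ann.charge)]
        transitions.append(
            Transition(
                precursor_mz=t.precursor_mz,
                product_mz=new_mz,
                library_intensity=t.library_intensity,
                annotation=FragmentIon(ann.series, ann.ordinal, ann.charge, new_mz),
                irt=t.irt,
                is_decoy=True,
                transition_name=f"{i}_{gid}_{ann.label}",
                peptide=decoy_peptide,
                charge=entry.key.charge,
                proteins=tuple(f"DECOY_{p}" for p in entry.proteins),
            )
        )
    return AssayEntry(
        key=decoy_key,
        transitions=transitions,
        irt=entry.irt,
        proteins=tuple(f"DECOY_{p}" for p in entry.proteins),
        is_decoy=True,
        n_replicates=entry.n_replicates,
        sample_type=entry.sample_type,
        best_score=entry.best_score,
        target_group_id=entry.group_id,
    )


def assemble_library(
    targets: Sequence[AssayEntry],
    decoy_method: str = "pseudo-reverse",
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> Library:
    """Append one decoy per target (where possible) and build the library."""
    if not targets:
        raise ValueError("assemble_library needs at least one target entry")
    entries: list[AssayEntry] = list(targets)
    decoys: list[AssayEntry] = []
    failures = 0
    target_seqs = {(e.key.peptide.sequence, e.key.charge) for e in targets}
    seen_decoy_ids: set[str] = set()
    for i, entry in enumerate(targets):
        try:
            decoy = generate_decoy(entry, method=decoy_method, seed=seed + i)
        except DecoyFailure:
            failures += 1
            continue
        if (decoy.key.peptide.sequence, decoy.key.charge) in target_seqs:
            failures += 1
            continue
        if decoy.group_id in seen_decoy_ids:  # two targets collapsing to one decoy
            failures += 1
            continue
        seen_decoy_ids.add(decoy.group_id)
        decoys.append(decoy)
    meta = dict(metadata or {})
    meta.update(
        {
            "decoy_method": decoy_method,
            "decoy_seed": seed,
            "n_targets": len(targets),
            "n_decoys": len(decoys),
            "decoy_failures": failures,
            "fragment_series": "b,y",
            "fragment_charges": "1,2",
        }
    )
    return Library(entries + decoys, metadata=meta)
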