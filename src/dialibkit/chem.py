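"""Peptide mass and fragment-ion chemistry.

Parsing of modified peptide sequences (UniMod bracket notation), monoisotopic
masses, precursor and b/y fragment m/z, and annotation of spectrum peaks with
fragment ions.  All masses are monoisotopic — the libraries this package
builds target high-resolution Orbitrap data, where average masses have no
place.  Fragment series are restricted to b and y at charge 1-2 by default,
the convention of DIA assay libraries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASSES",
    "UNIMOD_DELTAS",
    "ChemError",
    "ParseError",
    "UnsupportedModificationError",
    "Modification",
    "ModifiedPeptide",
    "PrecursorKey",
    "Peak",
    "Spectrum",
    "FragmentIon",
    "parse_modified_sequence",
    "monoisotopic_mass",
    "precursor_mz",
    "annotate_fragments",
    "match_peaks",
]

# Published monoisotopic residue masses (Da), 20 canonical amino acids.
RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

# Bundled UniMod subset: id -> (name, monoisotopic delta).  Covers the fixed
# and variable modifications of a standard tryptic search (carbamidomethyl-C,
# oxidised M, N-terminal acetylation) plus a few common extras.
UNIMOD_DELTAS: Mapping[int, tuple[str, float]] = {
    1: ("Acetyl", 42.010565),
    4: ("Carbamidomethyl", 57.021464),
    5: ("Carbamyl", 43.005814),
    7: ("Deamidated", 0.984016),
    21: ("Phospho", 79.966331),
    35: ("Oxidation", 15.994915),
}


class ChemError(ValueError):
    """Base error for peptide-chemistry failures."""


class ParseError(ChemError):
    """Raised for text that is not a valid modified-peptide string."""


class UnsupportedModificationError(ChemError):
    """Raised when a UniMod id is outside the bundled subset."""


@dataclass(frozen=True, order=True)
class Modification:
    """A positioned modification: 1-based residue index (0 = N-terminus)."""

    position: int
    unimod_id: int
    mass_delta: float


@dataclass(frozen=True)
class ModifiedPeptide:
    """An amino-acid sequence with positioned modifications."""

    sequence: str
    mods: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ChemError("empty peptide sequence")
        bad = set(self.sequence) - set(RESIDUE_MASSES)
        if bad:
            raise ParseError(f"non-canonical residue(s): {sorted(bad)}")
        positions = [m.position for m in self.mods]
        if len(positions) != len(set(positions)):
            raise ChemError("more than one modification at a position")
        for m in self.mods:
            if not 0 <= m.position <= len(self.sequence):
                raise ChemError(
                    f"modification position {m.position} outside [0, {len(self.sequence)}]"
                )
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_modified(self) -> bool:
        return bool(self.mods)

    def to_unimod_string(self) -> str:
        """Canonical text form with bracketed UniMod tags, N-term tag leading."""
        by_pos = {m.position: m for m in self.mods}
        out = []
        if 0 in by_pos:
            out.append(f"[UniMod:{by_pos[0].unimod_id}]")
        for i, res in enumerate(self.sequence, start=1):
            out.append(res)
            if i in by_pos:
                out.append(f"[UniMod:{by_pos[i].unimod_id}]")
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_unimod_string()


@dataclass(frozen=True)
class PrecursorKey:
    """Identity unit of a transition group: modified peptide + charge."""

    peptide: ModifiedPeptide
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ChemError(f"charge must be >= 1, got {self.charge}")

    @property
    def mz(self) -> float:
        return precursor_mz(self.peptide, self.charge)

    def __str__(self) -> str:
        return f"{self.peptide.to_unimod_string()}/{self.charge}"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ChemError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ChemError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A centroided peak list, sorted ascending by m/z."""

    peaks: list[Peak]
    precursor: Optional[PrecursorKey] = None
    rt_seconds: float = float("nan")
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion of a specific peptide."""

    series: str
    ordinal: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ChemError(f"unsupported fragment series {self.series!r}")
        if self.ordinal < 1:
            raise ChemError("fragment ordinal must be >= 1")
        if self.charge < 1:
            raise ChemError("fragment charge must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.series}{self.ordinal}^{self.charge}"


_TOKEN = re.compile(
    r"(?P<res>[A-Z])"
    r"(?:\[(?:UniMod:(?P<uid>\d+)|(?P<delta>[+-]\d+(?:\.\d+)?))\])?"
)
_NTERM = re.compile(r"^\[(?:UniMod:(?P<uid>\d+)|(?P<delta>[+-]\d+(?:\.\d+)?))\]-?")


def _resolve_delta(delta: float) -> tuple[int, float]:
    """Map a numeric mass delta to the nearest bundled UniMod entry (±0.01 Da)."""
    for uid, (_, d) in UNIMOD_DELTAS.items():
        if abs(d - delta) <= 0.01:
            return uid, d
    raise UnsupportedModificationError(f"no bundled UniMod entry near {delta:+.6f} Da")


def parse_modified_sequence(text: str) -> ModifiedPeptide:
    """Parse ``PEPTC[UniMod:4]IDE``-style text into a :class:`ModifiedPeptide`.

    Accepts UniMod bracket tags and numeric mass-delta tags (``C[+57.0215]``,
    normalised to the nearest bundled UniMod entry).  A leading bracket tag
    (optionally followed by ``-``) is an N-terminal modification.
    """
    if not text:
        raise ParseError("empty peptide string")
    mods: list[Modification] = []
    m = _NTERM.match(text)
    pos_text = text
    if m:
        uid, delta = _tag_to_mod(m.group("uid"), m.group("delta"))
        mods.append(Modification(0, uid, delta))
        pos_text = text[m.end():]
    residues: list[str] = []
    idx = 0
    for tok in _TOKEN.finditer(pos_text):
        if tok.start() != idx:
            raise ParseError(f"unparseable peptide text at offset {idx}: {pos_text!r}")
        idx = tok.end()
        res = tok.group("res")
        if res not in RESIDUE_MASSES:
            raise ParseError(f"non-canonical residue {res!r} in {text!r}")
        residues.append(res)
        if tok.group("uid") is not None or tok.group("delta") is not None:
            uid, delta = _tag_to_mod(tok.group("uid"), tok.group("delta"))
            mods.append(Modification(len(residues), uid, delta))
    if idx != len(pos_text) or not residues:
        raise ParseError(f"unparseable peptide text: {text!r}")
    return ModifiedPeptide("".join(residues), tuple(mods))


def _tag_to_mod(uid_text: Optional[str], delta_text: Optional[str]) -> tuple[int, float]:
    if uid_text is not None:
        uid = int(uid_text)
        if uid not in UNIMOD_DELTAS:
            raise UnsupportedModificationError(f"UniMod:{uid} not in bundled subset")
        return uid, UNIMOD_DELTAS[uid][1]
    return _resolve_delta(float(delta_text))


def monoisotopic_mass(peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    return (
        sum(RESIDUE_MASSES[r] for r in peptide.sequence)
        + WATER
        + sum(m.mass_delta for m in peptide.mods)
    )


def precursor_mz(peptide: ModifiedPeptide, charge: int) -> float:
    """m/z of the protonated precursor at the given charge."""
    if charge < 1:
        raise ChemError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(peptide) + charge * PROTON) / charge


def annotate_fragments(
    peptide: ModifiedPeptide, max_fragment_charge: int = 2
) -> list[FragmentIon]:
    """All b_i / y_i ions, i in 1..n-1, at fragment charges 1..max.

    N-terminal modifications ride with the b series; a modification on
    residue j contributes to b_i for i >= j and to y_i for i > n - j.
    """
    n = len(peptide)
    if n < 2:
        raise ChemError("fragmentation requires a peptide of length >= 2")
    if max_fragment_charge < 1:
        raise ChemError("max_fragment_charge must be >= 1")
    seq = peptide.sequence
    # prefix[i] = neutral mass of the first i residues incl. local mods
    prefix = [0.0]
    for res in seq:
        prefix.append(prefix[-1] + RESIDUE_MASSES[res])
    prefix = list(prefix)
    mod_prefix = [0.0] * (n + 1)
    nterm_delta = 0.0
    for m in peptide.mods:
        if m.position == 0:
            nterm_delta += m.mass_delta
        else:
            for i in range(m.position, n + 1):
                mod_prefix[i] += m.mass_delta
    total = monoisotopic_mass(peptide)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_neutral = prefix[i] + mod_prefix[i] + nterm_delta
        # complementary y ion spans the last n - i residues (water included)
        y_neutral = total - b_neutral
        for z in range(1, max_fragment_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", n - i, z, (y_neutral + z * PROTON) / z))
    return ions


def match_peaks(
    spectrum: Spectrum,
    ions: Sequence[FragmentIon],
    tol: float = 0.03,
) -> dict[FragmentIon, Peak]:
    """Match fragment ions to spectrum peaks within ±tol Th.

    Each ion takes its nearest peak; a peak satisfies at most one ion.
    Conflicts resolve by distance, then b before y, then lower ordinal,
    then lower fragment charge.
    """
    if tol <= 0:
        raise ChemError("tolerance must be positive")
    candidates: list[tuple[float, int, int, int, int, int]] = []
    for ii, ion in enumerate(ions):
        for pi, peak in enumerate(spectrum.peaks):
            d = abs(peak.mz - ion.mz)
            if d <= tol:
                series_rank = 0 if ion.series == "b" else 1
                candidates.append((d, series_rank, ion.ordinal, ion.charge, ii, pi))
    candidates.sort()
    matched: dict[FragmentIon, Peak] = {}
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    for _, _, _, _, ii, pi in candidates:
        if ii in used_ions or pi in used_peaks:
            continue
        used_ions.add(ii)
        used_peaks.add(pi)
        matched[ions[ii]] = spectrum.peaks[pi]
    return matched
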