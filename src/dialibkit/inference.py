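"""Protein grouping, proteotypicity, library statistics and abundance rollup.

A protein group is either a single protein identified by a peptide set not
contained in any other group, or a set of proteins sharing the same set or a
subset of identified peptides.  Operationally: accessions with identical
peptide sets merge, and an accession whose peptide set is a strict subset of
another's is absorbed into that superset's group, to closure.  A peptide is
proteotypic when it maps to exactly one accession; a protein counts as
proteotypic when it is Swiss-Prot canonical and owns at least one
proteotypic peptide.  Protein abundance in DIA output is rolled up as the
median of all fragment intensities of the precursors assigned to the group.
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PeptideProteinMap",
    "ProteinGroup",
    "LibraryStats",
    "build_protein_groups",
    "flag_proteotypic",
    "proteotypic_proteins",
    "library_stats",
    "intersect_and_cumulate",
    "protein_abundance_rollup",
    "read_fasta_accessions",
    "peptide_protein_map_from_library",
]


@dataclass
class PeptideProteinMap:
    """peptide sequence -> set of accessions, plus Swiss-Prot canonical flags."""

    mapping: dict[str, set[str]]
    is_swissprot_canonical: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pep, accs in self.mapping.items():
            if not accs:
                raise ValueError(f"peptide {pep!r} maps to no accession")

    @property
    def accessions(self) -> set[str]:
        out: set[str] = set()
        for accs in self.mapping.values():
            out |= accs
        return out


@dataclass(frozen=True)
class ProteinGroup:
    members: frozenset[str]
    peptide_set: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if not self.members or not self.peptide_set:
            raise ValueError("protein group must have members and peptides")


@dataclass(frozen=True)
class LibraryStats:
    n_transition_groups: int
    n_peptides: int
    n_stripped_peptides: int
    n_protein_groups: int
    n_proteotypic_proteins: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def build_protein_groups(pep_map: PeptideProteinMap) -> list[ProteinGroup]:
    """Group accessions by identical or subset peptide sets.

    Accessions with identical peptide sets merge; an accession whose set is
    a strict subset of another's is absorbed into the superset's group
    (ambiguity between incomparable supersets: the larger peptide set wins,
    ties by lexicographically smallest representative).  Deterministic under
    input order.
    """
    if not pep_map.mapping:
        return []
    acc_peps: dict[str, set[str]] = {}
    for pep, accs in pep_map.mapping.items():
        for acc in accs:
            acc_peps.setdefault(acc, set()).add(pep)

    # merge identical sets
    by_set: dict[frozenset[str], set[str]] = {}
    for acc, peps in acc_peps.items():
        by_set.setdefault(frozenset(peps), set()).add(acc)

    def representative(members: set[str]) -> str:
        canon = [a for a in members if pep_map.is_swissprot_canonical.get(a, False)]
        return min(canon) if canon else min(members)

    # order candidate groups: large peptide sets first, stable tie-break
    ordered = sorted(
        by_set.items(), key=lambda kv: (-len(kv[0]), representative(kv[1]))
    )
    maximal: list[tuple[frozenset[str], set[str]]] = []
    for peps, members in ordered:
        hosts = [
            i for i, (mp, _) in enumerate(maximal) if peps < mp
        ]
        if hosts:
            # absorb into the host with the largest peptide set, tie -> smallest
            # representative; `maximal` is already in that order
            maximal[hosts[0]][1].update(members)
        else:
            maximal.append((peps, set(members)))
    return [
        ProteinGroup(frozenset(members), peps, representative(members))
        for peps, members in maximal
    ]


def flag_proteotypic(pep_map: PeptideProteinMap) -> set[tuple[str, str]]:
    """(peptide, accession) pairs where the peptide maps to exactly one accession."""
    return {
        (pep, next(iter(accs)))
        for pep, accs in pep_map.mapping.items()
        if len(accs) == 1
    }


def proteotypic_proteins(pep_map: PeptideProteinMap) -> set[str]:
    """Swiss-Prot canonical accessions with >= 1 proteotypic peptide."""
    return {
        acc
        for _, acc in flag_proteotypic(pep_map)
        if pep_map.is_swissprot_canonical.get(acc, False)
    }


def library_stats(library, pep_map: Optional[PeptideProteinMap] = None) -> LibraryStats:
    """Headline counts of a library: precursors, peptides, groups, proteins.

    Decoy entries are excluded.  ``pep_map`` defaults to the map implied by
    the library's own protein annotations (accession canonicality inferred
    from ``sp|``-style accessions).
    """
    targets = library.targets
    if pep_map is None:
        pep_map = peptide_protein_map_from_library(library)
    keys = {e.key for e in targets}
    modified_seqs = {e.key.peptide.to_unimod_string() for e in targets}
    stripped_seqs = {e.key.peptide.sequence for e in targets}
    groups = build_protein_groups(pep_map) if pep_map.mapping else []
    return LibraryStats(
        n_transition_groups=len(keys),
        n_peptides=len(modified_seqs),
        n_stripped_peptides=len(stripped_seqs),
        n_protein_groups=len(groups),
        n_proteotypic_proteins=len(proteotypic_proteins(pep_map)),
    )


_SP_ACC = re.compile(r"^sp\|(?P<acc>[^|]+)\|")


def _accession_fields(acc: str) -> tuple[str, bool]:
    """Return (bare accession, canonical Swiss-Prot flag) for a header-style id.

    ``sp|P02741|CRP_HUMAN`` is canonical; ``sp|P02741-2|...`` (isoform
    suffix) and ``tr|...`` entries are not.
    """
    m = _SP_ACC.match(acc)
    if m:
        bare = m.group("acc")
        return bare, "-" not in bare
    return acc, False


def peptide_protein_map_from_library(library) -> PeptideProteinMap:
    mapping: dict[str, set[str]] = {}
    canonical: dict[str, bool] = {}
    for entry in library.targets:
        peps = mapping.setdefault(entry.key.peptide.sequence, set())
        for acc in entry.proteins:
            peps.add(acc)
            canonical[acc] = _accession_fields(acc)[1]
    return PeptideProteinMap(mapping, canonical)


def read_fasta_accessions(path) -> dict[str, bool]:
    """accession -> Swiss-Prot-canonical flag from FASTA headers."""
    out: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                acc = line[1:].split()[0]
                out[acc] = _accession_fields(acc)[1]
    return out


def intersect_and_cumulate(
    libraries: Sequence, names: Optional[Sequence[str]] = None
) -> dict:
    """Set algebra over libraries: per-set counts, pairwise intersections and
    cumulative union growth (peptides and protein-group representatives)."""
    if not libraries:
        raise ValueError("need at least one library")
    if names is None:
        names = [f"lib{i}" for i in range(len(libraries))]
    pep_sets = []
    prot_sets = []
    for lib in libraries:
        pm = peptide_protein_map_from_library(lib)
        pep_sets.append({e.key.peptide.to_unimod_string() for e in lib.targets})
        prot_sets.append({g.representative for g in build_protein_groups(pm)})
    result = {
        "names": list(names),
        "peptides": {n: len(s) for n, s in zip(names, pep_sets)},
        "proteins": {n: len(s) for n, s in zip(names, prot_sets)},
        "pairwise_peptide_intersections": {},
        "pairwise_protein_intersections": {},
        "common_peptides": len(set.intersection(*pep_sets)),
        "common_proteins": len(set.intersection(*prot_sets)),
        "cumulative_peptides": [],
        "cumulative_proteins": [],
    }
    for i in range(len(libraries)):
        for j in range(i + 1, len(libraries)):
            key = f"{names[i]}&{names[j]}"
            result["pairwise_peptide_intersections"][key] = len(pep_sets[i] & pep_sets[j])
            result["pairwise_protein_intersections"][key] = len(prot_sets[i] & prot_sets[j])
    acc_p: set[str] = set()
    acc_r: set[str] = set()
    for s_p, s_r in zip(pep_sets, prot_sets):
        acc_p |= s_p
        acc_r |= s_r
        result["cumulative_peptides"].append(len(acc_p))
        result["cumulative_proteins"].append(len(acc_r))
    return result


def protein_abundance_rollup(
    fragment_intensities: Mapping[str, Mapping[str, Sequence[float]]]
) -> dict[str, float]:
    """Protein abundance = median over all detected fragment intensities.

    Input maps protein-group id -> precursor id -> fragment intensity list;
    missing fragments are simply absent (never zero-filled).  Groups with no
    detected fragment are absent from the output.
    """
    out: dict[str, float] = {}
    for pg, by_prec in fragment_intensities.items():
        values = [v for frag_list in by_prec.values() for v in frag_list]
        if values:
            out[pg] = float(statistics.median(values))
    return out
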