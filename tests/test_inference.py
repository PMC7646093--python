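"""Protein grouping, proteotypicity, library statistics and abundance rollup."""

import itertools
import random

import pytest

from dialibkit.inference import (
    PeptideProteinMap,
    build_protein_groups,
    flag_proteotypic,
    intersect_and_cumulate,
    library_stats,
    protein_abundance_rollup,
    proteotypic_proteins,
)


def brute_force_groups(acc_peps: dict[str, frozenset]) -> set[frozenset]:
    """Oracle: exhaustive pairwise subset closure over accession peptide sets.

    Maximal sets are found by comparing every pair of distinct peptide sets;
    each accession is then assigned to the containing maximal set, resolving
    ambiguity by larger peptide set then lexicographically smallest owner —
    the same documented tie rule, realised by a different algorithm.
    """
    distinct = set(acc_peps.values())
    maximal = [s for s in distinct if not any(s < t for t in distinct)]

    def owner(s: frozenset) -> str:
        return min(a for a, peps in acc_peps.items() if peps == s)

    maximal.sort(key=lambda s: (-len(s), owner(s)))
    groups: dict[frozenset, set[str]] = {m: set() for m in maximal}
    for acc, peps in acc_peps.items():
        host = next(m for m in maximal if peps <= m)
        groups[host].add(acc)
    return {frozenset(members) for members in groups.values() if members}


def pmap(mapping, canonical=None):
    return PeptideProteinMap(
        {p: set(a) for p, a in mapping.items()},
        canonical or {},
    )


class TestProteinGroups:
    def test_identical_sets_merge(self):
        groups = build_protein_groups(pmap({"a": ["P1", "P2"], "b": ["P1", "P2"]}))
        assert len(groups) == 1
        assert groups[0].members == frozenset({"P1", "P2"})

    def test_subset_absorbed(self):
        groups = build_protein_groups(
            pmap({"a": ["P1", "P2"], "b": ["P1", "P2"], "c": ["P1"]})
        )
        assert len(groups) == 1
        assert groups[0].peptide_set == frozenset({"a", "b", "c"})

    def test_disjoint_sets_stay_separate(self):
        groups = build_protein_groups(pmap({"a": ["P1"], "b": ["P2"]}))
        assert len(groups) == 2

    def test_chain_plus_disjoint(self):
        # P1 > P2 > P3 nested, P4 disjoint: brute-force closure gives 2 groups
        mapping = {
            "a": ["P1"], "b": ["P1", "P2"], "c": ["P1", "P2", "P3"],
            "d": ["P4"],
        }
        groups = build_protein_groups(pmap(mapping))
        assert len(groups) == 2
        big = next(g for g in groups if "P1" in g.members)
        assert big.members == frozenset({"P1", "P2", "P3"})

    def test_union_covers_all_peptides_and_members_disjoint(self):
        rng = random.Random(0)
        mapping = {
            f"pep{i}": rng.sample([f"P{j}" for j in range(8)], rng.randint(1, 3))
            for i in range(25)
        }
        groups = build_protein_groups(pmap(mapping))
        all_peps = set().union(*(g.peptide_set for g in groups))
        assert all_peps == set(mapping)
        members = [g.members for g in groups]
        for a, b in itertools.combinations(members, 2):
            assert not (a & b)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        n_acc = rng.randint(2, 12)
        accs = [f"P{i}" for i in range(n_acc)]
        mapping = {}
        for i in range(rng.randint(3, 25)):
            mapping[f"pep{i}"] = rng.sample(accs, rng.randint(1, min(4, n_acc)))
        used = {a for accs_ in mapping.values() for a in accs_}
        acc_peps = {
            a: frozenset(p for p, accs_ in mapping.items() if a in accs_) for a in used
        }
        ours = {g.members for g in build_protein_groups(pmap(mapping))}
        assert ours == brute_force_groups(acc_peps)


class TestProteotypic:
    def test_unique_peptide_is_proteotypic(self):
        pairs = flag_proteotypic(pmap({"a": ["P1"], "b": ["P1", "P2"]}))
        assert pairs == {("a", "P1")}

    def test_protein_needs_canonical_flag_and_unique_peptide(self):
        m = pmap(
            {"a": ["P1"], "b": ["P2"], "c": ["P3", "P1"]},
            canonical={"P1": True, "P2": False, "P3": True},
        )
        # P1 canonical with unique peptide; P2 unique but not canonical;
        # P3 canonical but only shared peptides
        assert proteotypic_proteins(m) == {"P1"}


class TestLibraryStats:
    def _library(self):
        from dialibkit.assays import assemble_library, select_transitions
        from test_assays import consensus_from_ions

        # 8 precursors over 6 peptides; 5 accessions with known subset structure
        spec = [
            ("LATQSNEITIPVTFESR", 2, ("sp|P1|A_HUMAN",)),
            ("LATQSNEITIPVTFESR", 3, ("sp|P1|A_HUMAN",)),
            ("ESDTSYVSLK", 2, ("sp|P1|A_HUMAN", "sp|P2|B_HUMAN")),
            ("SGDFGPEVTR", 2, ("sp|P2|B_HUMAN", "sp|P1|A_HUMAN")),
            ("GAVLIWDK", 2, ("sp|P3|C_HUMAN",)),
            ("GAVLIWDK", 3, ("sp|P3|C_HUMAN",)),
            ("MNQSTVWK", 2, ("sp|P4|D_HUMAN",)),
            ("FHPEVLTK", 2, ("sp|P5|E_HUMAN",)),
        ]
        targets = []
        for seq, z, prots in spec:
            cs = consensus_from_ions(seq, charge=z, n_ions=3)
            cs.proteins = prots
            entry = select_transitions(cs)
            entry = type(entry)(
                key=entry.key, transitions=entry.transitions, irt=entry.irt,
                proteins=prots, is_decoy=False, n_replicates=1,
            )
            targets.append(entry)
        return assemble_library(targets, seed=0)

    def test_counts_match_hand_enumeration(self):
        lib = self._library()
        stats = library_stats(lib)
        # by hand: 8 precursors, 6 modified sequences; P1 ⊃ P2 (P2's peptides
        # {ESDTSYVSLK, SGDFGPEVTR} ⊂ P1's) so P1+P2 one group, P3, P4, P5
        # separate -> 4 groups; proteotypic canonical proteins: P1 (via
        # LATQSNEITIPVTFESR), P3, P4, P5 -> 4
        assert stats.n_transition_groups == 8
        assert stats.n_peptides == 6
        assert stats.n_protein_groups == 4
        assert stats.n_proteotypic_proteins == 4

    def test_decoys_do_not_count(self):
        lib = self._library()
        with_decoys = library_stats(lib)
        from dialibkit.assays import Library

        targets_only = Library(lib.targets, metadata={})
        assert library_stats(targets_only) == with_decoys

    def test_empty_library_all_zero(self):
        from dialibkit.assays import Library

        stats = library_stats(Library([], metadata={}))
        assert (
            stats.n_transition_groups, stats.n_peptides,
            stats.n_protein_groups, stats.n_proteotypic_proteins,
        ) == (0, 0, 0, 0)


class TestIntersectCumulate:
    def _libs(self):
        lib = TestLibraryStats()._library()
        return lib

    def test_identical_libraries_flat_curve(self):
        lib = self._libs()
        out = intersect_and_cumulate([lib, lib], names=["x", "y"])
        assert out["common_peptides"] == out["peptides"]["x"]
        assert out["cumulative_peptides"][0] == out["cumulative_peptides"][1]

    def test_disjoint_libraries_additive(self):
        from dialibkit.assays import Library

        lib = self._libs()
        half1 = Library(lib.targets[:4], metadata={})
        half2 = Library(lib.targets[4:], metadata={})
        out = intersect_and_cumulate([half1, half2])
        assert out["pairwise_peptide_intersections"]["lib0&lib1"] == 0
        assert out["cumulative_peptides"][-1] == out["peptides"]["lib0"] + out["peptides"]["lib1"]


class TestAbundanceRollup:
    def test_odd_median(self):
        out = protein_abundance_rollup({"G1": {"prec1": [10.0, 20.0, 30.0]}})
        assert out["G1"] == 20.0

    def test_even_median_mean_of_central_pair(self):
        out = protein_abundance_rollup({"G1": {"p1": [10.0, 20.0], "p2": [30.0, 100.0]}})
        assert out["G1"] == 25.0

    def test_independent_groups_and_absent_when_empty(self):
        out = protein_abundance_rollup(
            {"G1": {"p1": [10.0]}, "G2": {"p2": [99.0]}, "G3": {"p3": []}}
        )
        assert out == {"G1": 10.0, "G2": 99.0}
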