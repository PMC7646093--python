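"""Serialization (OpenSWATH TSV, TraML), PRM schedules, merge and subset."""

import xml.etree.ElementTree as ET

import pytest

from dialibkit.assays import Library, assemble_library, select_transitions
from dialibkit.landmarks import CalibrationFit, assign_reference_irt, select_cirt
from dialibkit.library_io import (
    OPENSWATH_COLUMNS,
    LibraryParseError,
    PRMScheduleConfig,
    export_prm_schedule,
    merge_libraries,
    read_openswath_tsv,
    subset_library,
    validate_traml,
    write_openswath_tsv,
    write_traml,
)
from dialibkit.simulate import dense_cirt_run

from test_assays import consensus_from_ions


def small_library(seqs=("LATQSNEITIPVTFESR", "ESDTSYVSLK", "SGDFGPEVTR"), seed=0,
                  sample_type="tissue", score=77.0):
    targets = []
    for seq in seqs:
        cs = consensus_from_ions(seq, n_ions=4)
        cs.sample_type = sample_type
        cs.best_score = score
        entry = select_transitions(cs)
        entry.sample_type = sample_type
        entry.best_score = score
        targets.append(entry)
    return assemble_library(targets, seed=seed)


class TestOpenswathTsv:
    def test_roundtrip_is_identity(self, tmp_path):
        lib = small_library()
        path = tmp_path / "lib.tsv"
        write_openswath_tsv(lib, path)
        back = read_openswath_tsv(path)
        assert len(back.entries) == len(lib.entries)
        by_id = {e.group_id: e for e in back.entries}
        for entry in lib.entries:
            other = by_id[entry.group_id]
            assert other.key == entry.key
            assert other.irt == entry.irt
            assert other.proteins == entry.proteins
            assert other.is_decoy == entry.is_decoy
            assert other.n_replicates == entry.n_replicates
            assert other.sample_type == entry.sample_type
            assert other.target_group_id == entry.target_group_id
            assert [
                (t.product_mz, t.library_intensity, t.annotation.series,
                 t.annotation.ordinal, t.annotation.charge, t.transition_name)
                for t in other.transitions
            ] == [
                (t.product_mz, t.library_intensity, t.annotation.series,
                 t.annotation.ordinal, t.annotation.charge, t.transition_name)
                for t in entry.transitions
            ]

    def test_decoy_column_marks_exactly_decoys(self, tmp_path):
        import pandas as pd

        lib = small_library()
        path = tmp_path / "lib.tsv"
        write_openswath_tsv(lib, path)
        df = pd.read_csv(path, sep="\t")
        assert set(OPENSWATH_COLUMNS) <= set(df.columns)
        decoy_rows = df[df["decoy"] == 1]
        assert (decoy_rows["transition_name"].str.contains("DECOY_")).all()
        assert not df[df["decoy"] == 0]["transition_name"].str.contains("DECOY_").any()

    def test_row_count_is_total_transitions(self, tmp_path):
        import pandas as pd

        lib = small_library()
        path = tmp_path / "lib.tsv"
        write_openswath_tsv(lib, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == sum(len(e.transitions) for e in lib.entries)

    def test_missing_column_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("PrecursorMz\tProductMz\n100\t200\n")
        with pytest.raises(LibraryParseError, match="missing"):
            read_openswath_tsv(path)


class TestTraml:
    def test_library_traml_validates(self, tmp_path):
        path = tmp_path / "lib.traml"
        write_traml(small_library(), path)
        validate_traml(path)

    def test_cirt_landmark_traml_has_20_peptides(self, tmp_path):
        landmarks = assign_reference_irt(select_cirt(dense_cirt_run(1000, seed=4)))
        path = tmp_path / "cirt.traml"
        write_traml(landmarks, path)
        validate_traml(path)
        ns = {"t": "http://psi.hupo.org/ms/traml"}
        root = ET.parse(path).getroot()
        peptides = root.findall("./t:CompoundList/t:Peptide", ns)
        assert len(peptides) == 20
        rts = root.findall(".//t:RetentionTime/t:cvParam[@accession='MS:1000896']", ns)
        assert len(rts) == 20

    def test_empty_library_is_valid_traml(self, tmp_path):
        path = tmp_path / "empty.traml"
        write_traml(Library([], metadata={}), path)
        validate_traml(path)

    def test_independent_parser_preserves_mz(self, tmp_path):
        # read back with stdlib ElementTree (no shared code with the writer)
        lib = small_library()
        path = tmp_path / "lib.traml"
        write_traml(lib, path)
        ns = {"t": "http://psi.hupo.org/ms/traml"}
        root = ET.parse(path).getroot()
        parsed = []
        for tr in root.findall("./t:TransitionList/t:Transition", ns):
            prec = tr.find("./t:Precursor/t:cvParam[@accession='MS:1000827']", ns)
            prod = tr.find("./t:Product/t:cvParam[@accession='MS:1000827']", ns)
            parsed.append((float(prec.attrib["value"]), float(prod.attrib["value"])))
        expected = [
            (t.precursor_mz, t.product_mz)
            for e in lib.entries
            for t in e.transitions
        ]
        assert len(parsed) == len(expected)
        for (p1, q1), (p2, q2) in zip(parsed, expected):
            assert abs(p1 - p2) <= 1e-4 and abs(q1 - q2) <= 1e-4


class TestPrmSchedule:
    def _fit(self):
        # iRT = rt/36 - 10  =>  rt = (irt + 10) * 36 seconds
        return CalibrationFit(slope=1 / 36.0, intercept=-10.0, r_squared=1.0, n_points_used=3)

    def test_window_width_is_twice_halfwidth(self):
        lib = small_library()
        schedule, missing, warnings = export_prm_schedule(
            lib, ["ESDTSYVSLK"], self._fit(), PRMScheduleConfig(rt_halfwidth_minutes=5.0)
        )
        assert not missing
        row = schedule.iloc[0]
        assert row["End [min]"] - row["Start [min]"] == pytest.approx(10.0)
        center = (row["End [min]"] + row["Start [min]"]) / 2
        assert center == pytest.approx((42.0 + 10.0) * 36.0 / 60.0, abs=1e-2)

    def test_concurrency_warning_above_capacity(self):
        import random

        rng = random.Random(0)
        targets, seen = [], set()
        while len(targets) < 101:
            s = "".join(rng.choice("ACDEFGHILMNQSTVWY") for _ in range(9)) + "K"
            if s in seen:
                continue
            seen.add(s)
            try:
                cs = consensus_from_ions(s, n_ions=3, irt=50.0)
            except AssertionError:
                continue
            targets.append(select_transitions(cs))
        lib = Library(targets, metadata={})
        schedule, _, warnings = export_prm_schedule(
            lib,
            [e.key.peptide.sequence for e in targets],
            self._fit(),
            PRMScheduleConfig(max_concurrent_precursors=100),
        )
        assert len(schedule) >= 101
        assert warnings and "concurrent" in warnings[0]

    def test_absent_peptide_reported_not_dropped(self):
        lib = small_library()
        schedule, missing, _ = export_prm_schedule(
            lib, ["ESDTSYVSLK", "NOTINLIBK"], self._fit()
        )
        assert missing == ["NOTINLIBK"]
        assert len(schedule) == 1


class TestMergeSubset:
    def test_merge_idempotent(self):
        lib = small_library()
        merged = merge_libraries([lib, lib])
        assert sorted(e.group_id for e in merged.entries) == sorted(
            e.group_id for e in lib.entries
        )

    def test_merge_disjoint_additive(self):
        l1 = small_library(("LATQSNEITIPVTFESR", "ESDTSYVSLK"))
        l2 = small_library(("SGDFGPEVTR", "GAVLIWDK"))
        merged = merge_libraries([l1, l2])
        assert len(merged) == len(l1) + len(l2)

    def test_conflict_higher_best_score_wins(self):
        low = small_library(("ESDTSYVSLK",), score=10.0)
        high = small_library(("ESDTSYVSLK",), score=20.0)
        merged = merge_libraries([low, high], conflict_rule="higher_best_score")
        assert merged.targets[0].best_score == 20.0

    def test_merge_keep_first_associative(self):
        libs = [
            small_library(("ESDTSYVSLK", "SGDFGPEVTR"), score=1.0),
            small_library(("ESDTSYVSLK",), score=2.0),
            small_library(("GAVLIWDK",), score=3.0),
        ]
        a = merge_libraries([merge_libraries(libs[:2], "keep_first"), libs[2]], "keep_first")
        b = merge_libraries([libs[0], merge_libraries(libs[1:], "keep_first")], "keep_first")
        assert sorted((e.group_id, e.best_score) for e in a.entries) == sorted(
            (e.group_id, e.best_score) for e in b.entries
        )

    def test_subset_preserves_decoy_pairing(self):
        lib = small_library()
        sub = subset_library(lib, peptides=["ESDTSYVSLK"])
        assert len(sub.targets) == 1
        assert len(sub.decoys) == 1
        assert sub.decoys[0].target_group_id == sub.targets[0].group_id

    def test_subset_conjunction_equals_composition(self):
        lib = small_library()
        one = subset_library(
            subset_library(lib, sample_types=["tissue"]), peptides=["ESDTSYVSLK"]
        )
        both = subset_library(lib, sample_types=["tissue"], peptides=["ESDTSYVSLK"])
        assert sorted(e.group_id for e in one.entries) == sorted(
            e.group_id for e in both.entries
        )
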