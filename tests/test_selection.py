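"""The abundance-threshold + binding-composition candidate screen."""

import numpy as np
import pandas as pd
import pytest

from nucleoprofiler.selection import (SelectionConfig, SelectionResult,
                                      abundance_threshold, build_candidate_table,
                                      intersect_replicates, screen_uncharacterised,
                                      select_candidates, write_report)


def d_records(values, rep="rep1"):
    return pd.DataFrame({"accession": [f"D{i:03d}" for i in range(len(values))],
                         "replicate": rep, "empai": values, "category": "D"})


class TestAbundanceThreshold:
    def test_top_n_and_threshold_value(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.01, 10, size=40)
        out = abundance_threshold(d_records(vals), top_n_d=30)
        selected, thr = out["rep1"]
        assert len(selected) == 30
        assert thr == pytest.approx(np.sort(vals)[::-1][29])

    def test_fewer_than_top_n_selects_all_with_warning(self):
        with pytest.warns(UserWarning, match="selecting all"):
            out = abundance_threshold(d_records([3.0, 1.0, 2.0]), top_n_d=30)
        selected, thr = out["rep1"]
        assert len(selected) == 3
        assert thr == pytest.approx(1.0)

    def test_threshold_nonincreasing_in_top_n(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = rng.uniform(0, 5, size=50)
            thresholds = [abundance_threshold(d_records(vals), n)["rep1"][1]
                          for n in range(1, 51)]
            assert all(b <= a for a, b in zip(thresholds, thresholds[1:]))

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            abundance_threshold(d_records([1.0]), 0)


class TestScreenUncharacterised:
    def _u(self, values, rep="rep1"):
        return pd.DataFrame({"accession": [f"U{i:03d}" for i in range(len(values))],
                             "replicate": rep, "empai": values, "category": "U"})

    def test_requires_both_abundance_and_binding(self):
        u = self._u([2.0, 2.0, 0.5])
        scores = {"U000": 0.5, "U001": -0.5, "U002": 3.0}
        out = screen_uncharacterised(u, {"rep1": 1.0}, scores)
        assert out["rep1"] == {"U000"}

    def test_empai_equal_to_threshold_excluded(self):
        u = self._u([1.0])
        out = screen_uncharacterised(u, {"rep1": 1.0}, {"U000": 5.0})
        assert out["rep1"] == set()

    def test_score_exactly_zero_excluded(self):
        u = self._u([2.0])
        out = screen_uncharacterised(u, {"rep1": 1.0}, {"U000": 0.0})
        assert out["rep1"] == set()

    def test_missing_score_above_threshold_is_error(self):
        u = self._u([2.0, 2.0])
        with pytest.raises(KeyError, match="U001"):
            screen_uncharacterised(u, {"rep1": 1.0}, {"U000": 1.0})

    def test_missing_score_below_threshold_is_fine(self):
        u = self._u([2.0, 0.5])
        out = screen_uncharacterised(u, {"rep1": 1.0}, {"U000": 1.0})
        assert out["rep1"] == {"U000"}

    def test_empty_input(self):
        out = screen_uncharacterised(self._u([]), {"rep1": 1.0}, {})
        assert out == {}


class TestIntersectReplicates:
    def test_basic(self):
        assert intersect_replicates({"rep1": {"A", "B", "C"},
                                     "rep2": {"B", "C", "D"}}) == {"B", "C"}

    def test_identical_sets_unchanged(self):
        s = {"A", "B"}
        assert intersect_replicates({"rep1": set(s), "rep2": set(s)}) == s

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            intersect_replicates({"rep1": {"A"}})

    def test_protein_in_one_replicate_only_is_dropped(self):
        # a protein detected only in replicate 1 is treated as a contaminant
        assert "A" not in intersect_replicates({"rep1": {"A", "B"}, "rep2": {"B"}})


def two_rep_abundance():
    rows = []
    for rep in ("rep1", "rep2"):
        for i, v in enumerate([4.0, 3.0, 2.0, 1.0]):
            rows.append((f"D{i:03d}", rep, v, "D"))
        for i, v in enumerate([3.5, 0.2]):
            rows.append((f"U{i:03d}", rep, v, "U"))
    return pd.DataFrame(rows, columns=["accession", "replicate", "empai", "category"])


class TestBuildCandidateTable:
    def test_collision_between_d_and_u_rejected(self):
        ab = two_rep_abundance()
        with pytest.raises(ValueError, match="both D and U"):
            build_candidate_table({"D000"}, {"D000"}, ab)

    def test_empty_selection_gives_empty_table(self):
        table = build_candidate_table(set(), set(), two_rep_abundance())
        assert len(table) == 0
        assert "accession" in table.columns

    def test_amalgamated_rank_over_merged_pool(self):
        ab = two_rep_abundance()
        table = build_candidate_table({"D000", "D001"}, {"U000"}, ab,
                                      binding_scores={"U000": 1.0})
        assert list(table["accession"]) == ["D000", "U000", "D001"]
        assert list(table["rank_rep1"]) == [1, 2, 3]

    def test_known_nap_flags_and_binding_score_assignment(self):
        ab = two_rep_abundance()
        table = build_candidate_table({"D000"}, {"U000"}, ab,
                                      known_naps={"D000"},
                                      binding_scores={"U000": 0.7})
        by_acc = table.set_index("accession")
        assert bool(by_acc.loc["D000", "known_nap"]) is True
        assert np.isnan(by_acc.loc["D000", "binding_score"])  # D rows carry no score
        assert by_acc.loc["U000", "binding_score"] == pytest.approx(0.7)

    def test_physchem_passthrough(self):
        ab = two_rep_abundance()
        phys = pd.DataFrame({"accession": ["D000"], "mw_kda": [9.9], "pi": [9.5]})
        table = build_candidate_table({"D000"}, set(), ab, physchem=phys)
        assert table.loc[0, "mw_kda"] == pytest.approx(9.9)
        assert table.loc[0, "pi"] == pytest.approx(9.5)


class TestSelectCandidates:
    def test_invariants_on_result(self):
        ab = two_rep_abundance()
        with pytest.warns(UserWarning):
            res = select_candidates(ab, SelectionConfig(top_n_d=30),
                                    {"U000": 1.0, "U001": 1.0})
        t = res.candidates
        assert set(t["category"]) <= {"D", "U"}
        # every candidate present in both replicates
        assert t[["rank_rep1", "rank_rep2"]].notna().all().all()
        # U candidates all passed the binding screen
        assert (t.loc[t.category == "U", "binding_score"] > 0).all()

    def test_candidates_monotone_in_top_n_d(self):
        import warnings

        ab = two_rep_abundance()
        sets = []
        for n in (1, 2, 3, 4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = select_candidates(ab, SelectionConfig(top_n_d=n), {"U000": 1.0})
            sets.append(set(res.candidates.loc[res.candidates.category == "D",
                                               "accession"]))
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_replicate_specific_dropout_excluded(self):
        ab = two_rep_abundance()
        # D999 abundant in rep1 only
        ab = pd.concat([ab, pd.DataFrame([("D999", "rep1", 10.0, "D")],
                                         columns=ab.columns)], ignore_index=True)
        with pytest.warns(UserWarning):
            res = select_candidates(ab, SelectionConfig(top_n_d=30), {"U000": 1.0})
        assert "D999" not in set(res.candidates["accession"])


class TestWriteReport:
    def _result(self):
        ab = two_rep_abundance()
        with pytest.warns(UserWarning):
            return select_candidates(ab, SelectionConfig(), {"U000": 1.0, "U001": 1.0})

    def test_report_files_and_determinism(self, tmp_path):
        res = self._result()
        p1 = write_report(res, tmp_path / "a")
        p2 = write_report(res, tmp_path / "b")
        assert p1["candidates"].read_bytes() == p2["candidates"].read_bytes()
        assert "final candidates" in p1["summary"].read_text()

    def test_empty_candidates_header_only(self, tmp_path):
        ab = two_rep_abundance()
        res = SelectionResult(candidates=build_candidate_table(set(), set(), ab),
                              d_sets={"rep1": set(), "rep2": set()},
                              u_sets={}, thresholds={"rep1": 1.0, "rep2": 1.0},
                              config=SelectionConfig())
        paths = write_report(res, tmp_path)
        lines = paths["candidates"].read_text().strip().splitlines()
        assert len(lines) == 1  # header only
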