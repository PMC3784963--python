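"""emPAI computation, ranking, and composition summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_evidence
from nucleoprofiler.empai import (composition_summary, compute_empai,
                                  filter_evidence, rank_by_empai, read_evidence)


class TestReadEvidence:
    def _write(self, tmp_path, text, name="ev.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_well_formed(self, tmp_path):
        p = self._write(tmp_path, "accession\tpeptide\texpect\treplicate\tslice\n"
                                  "A1\tPEPTIDEK\t0.01\trep1\tS1\n"
                                  "A1\tLLLGGGK\t0.02\trep1\tS2\n"
                                  "A2\tMMMNNNR\t0.03\trep2\tS1\n")
        df = read_evidence(p)
        assert len(df) == 3
        assert list(df.columns) == ["accession", "peptide", "expect", "replicate", "slice"]

    def test_missing_column_named(self, tmp_path):
        p = self._write(tmp_path, "accession\tpeptide\treplicate\tslice\nA1\tPK\trep1\tS1\n")
        with pytest.raises(ValueError, match="expect"):
            read_evidence(p)

    def test_negative_expect_rejected(self, tmp_path):
        p = self._write(tmp_path, "accession\tpeptide\texpect\treplicate\tslice\n"
                                  "A1\tPEPTIDEK\t-0.1\trep1\tS1\n")
        with pytest.raises(ValueError, match="expect"):
            read_evidence(p)

    def test_extra_columns_ignored(self, tmp_path):
        p = self._write(tmp_path, "accession\tpeptide\texpect\treplicate\tslice\tscore\n"
                                  "A1\tPEPTIDEK\t0.01\trep1\tS1\t55\n")
        df = read_evidence(p)
        assert "score" not in df.columns


class TestFilterEvidence:
    def test_threshold_boundary_inclusive(self):
        ev = make_evidence([("A1", "PEPK", e, "rep1", "S1")
                            for e in (0.01, 0.05, 0.06)])
        kept = filter_evidence(ev, 0.05)
        assert len(kept) == 2
        assert "slice" not in kept.columns

    def test_empty_input(self):
        assert len(filter_evidence(make_evidence([]), 0.05)) == 0

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_evidence(make_evidence([]), 0.0)


class TestComputeEmpai:
    def test_formula_via_controlled_denominator(self, small_proteome):
        ev = make_evidence([("A0001", f"PEP{i}K", 0.01, "rep1", "S1") for i in range(4)])
        ev = filter_evidence(ev)
        rec = compute_empai(ev, small_proteome, observable_counts={"A0001": 4})
        assert rec.loc[0, "pai"] == pytest.approx(1.0)
        assert rec.loc[0, "empai"] == pytest.approx(9.0)  # 10^1 - 1

    def test_half_coverage(self, small_proteome):
        ev = filter_evidence(make_evidence(
            [("A0001", "PEPAK", 0.01, "rep1", "S1"),
             ("A0001", "LLLGK", 0.01, "rep1", "S1")]))
        rec = compute_empai(ev, small_proteome, observable_counts={"A0001": 4})
        assert rec.loc[0, "empai"] == pytest.approx(10 ** 0.5 - 1, abs=1e-9)

    def test_peptide_in_two_slices_counts_once(self, small_proteome):
        ev = filter_evidence(make_evidence(
            [("A0001", "PEPAK", 0.01, "rep1", "S1"),
             ("A0001", "PEPAK", 0.01, "rep1", "S2")]))
        rec = compute_empai(ev, small_proteome, observable_counts={"A0001": 4})
        assert rec.loc[0, "n_observed"] == 1

    def test_undetected_protein_absent_not_zero(self, small_proteome):
        ev = filter_evidence(make_evidence([("A0001", "PEPAK", 0.01, "rep1", "S1")]))
        rec = compute_empai(ev, small_proteome, observable_counts={"A0001": 4})
        assert set(rec["accession"]) == {"A0001"}

    def test_unknown_accession_listed(self, small_proteome):
        ev = filter_evidence(make_evidence([("ZZZZ", "PEPAK", 0.01, "rep1", "S1")]))
        with pytest.raises(KeyError, match="ZZZZ"):
            compute_empai(ev, small_proteome)

    def test_denominator_from_digestion(self, small_proteome):
        # without an override the denominator comes from the in-silico digest
        ev = filter_evidence(make_evidence([("A0002", "VLITDEIR", 0.01, "rep1", "S1")]))
        rec = compute_empai(ev, small_proteome)
        assert rec.loc[0, "n_observable"] >= 1
        assert rec.loc[0, "pai"] == pytest.approx(1 / rec.loc[0, "n_observable"])

    def test_monotonicity_in_counts(self):
        def empai(n_obs, n_obsbl):
            return 10 ** (n_obs / n_obsbl) - 1

        assert empai(3, 10) > empai(2, 10)
        assert empai(2, 12) < empai(2, 10)
        assert empai(0, 10) == 0


class TestRankByEmpai:
    def _records(self, vals, rep="rep1"):
        return pd.DataFrame({"accession": [f"A{i}" for i in range(len(vals))],
                             "replicate": rep, "empai": vals})

    def test_descending_permutation(self):
        ranked = rank_by_empai(self._records([0.5, 3.0, 1.2]))
        assert sorted(ranked["rank"]) == [1, 2, 3]
        assert ranked.loc[ranked["accession"] == "A1", "rank"].item() == 1

    def test_ties_broken_by_accession(self):
        ranked = rank_by_empai(self._records([1.0, 1.0, 1.0]))
        by_acc = ranked.set_index("accession")["rank"]
        assert list(by_acc.loc[["A0", "A1", "A2"]]) == [1, 2, 3]

    def test_single_record(self):
        assert rank_by_empai(self._records([2.0]))["rank"].item() == 1

    def test_scope_predicate(self):
        df = self._records([1.0, 2.0, 3.0])
        df["category"] = ["D", "U", "D"]
        ranked = rank_by_empai(df, scope=lambda r: r["category"] == "D")
        assert set(ranked["accession"]) == {"A0", "A2"}
        assert ranked.loc[ranked["accession"] == "A2", "rank"].item() == 1

    def test_ranks_independent_per_replicate(self):
        df = pd.concat([self._records([1.0, 2.0], "rep1"),
                        self._records([5.0], "rep2")], ignore_index=True)
        ranked = rank_by_empai(df)
        assert set(ranked.loc[ranked.replicate == "rep1", "rank"]) == {1, 2}
        assert set(ranked.loc[ranked.replicate == "rep2", "rank"]) == {1}


class TestCompositionSummary:
    def _records(self):
        return pd.DataFrame({"accession": ["A0", "A1"], "replicate": "rep1",
                             "empai": [3.0, 1.0]})

    def test_two_category_split(self):
        out = composition_summary(self._records(), {"A0": "R", "A1": "D"})
        by_cat = out.set_index("category")["percent"]
        assert by_cat["R"] == pytest.approx(75.0)
        assert by_cat["D"] == pytest.approx(25.0)

    def test_single_category_is_100(self):
        out = composition_summary(self._records(), {"A0": "E", "A1": "E"})
        assert out["percent"].item() == pytest.approx(100.0)

    def test_percentages_sum_to_100_and_order_invariant(self):
        recs = pd.DataFrame({"accession": [f"A{i}" for i in range(6)],
                             "replicate": ["rep1"] * 3 + ["rep2"] * 3,
                             "empai": [3.0, 1.0, 0.5, 2.0, 2.0, 0.1]})
        cats = {f"A{i}": c for i, c in enumerate("RDUECR")}
        out = composition_summary(recs, cats)
        shuffled = composition_summary(recs.sample(frac=1, random_state=0), cats)
        for rep, grp in out.groupby("replicate"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        merged = out.merge(shuffled, on=["replicate", "category"], suffixes=("", "_s"))
        assert np.allclose(merged["percent"], merged["percent_s"])

    def test_unannotated_defaults_to_u(self):
        out = composition_summary(self._records(), {"A0": "R"})
        assert set(out["category"]) == {"R", "U"}
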