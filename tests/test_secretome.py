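"""Filtering, imputation and differential testing of the secretome matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from cmannose import (
    ImputeConfig,
    LfqMatrix,
    differential_test,
    filter_secretome,
    log2_and_impute,
    per_clone_fold_changes,
)


class TestFilter:
    def test_hand_traced_fixture_stagewise_counts(self, toy_matrix):
        matrix, gocc = toy_matrix
        filtered, report = filter_secretome(matrix, gocc)
        assert report.initial == 6
        assert report.after_decoy_removal == 4       # G1 (contaminant), G2 (reverse) out
        assert report.after_extracellular == 3       # G3 not extracellular
        assert report.after_identification == 1      # G4 single peptide, G5 detected once
        assert report.final == 1
        assert list(filtered.group_ids) == ["G6"]
        assert report.detected_in_all_lines == 1

    def test_filter_counts_never_increase(self, toy_matrix):
        matrix, gocc = toy_matrix
        _, report = filter_secretome(matrix, gocc)
        seq = [
            report.initial,
            report.after_decoy_removal,
            report.after_extracellular,
            report.after_identification,
            report.final,
        ]
        assert seq == sorted(seq, reverse=True)

    def test_empty_table_gives_zeroed_report(self, toy_design):
        cols = list(toy_design.all_samples)
        empty = LfqMatrix(
            pd.DataFrame(columns=cols, dtype=float),
            pd.DataFrame(
                columns=["members", "peptides", "contaminant", "reverse", "only_by_site"]
            ),
            toy_design,
        )
        filtered, report = filter_secretome(empty, {})
        assert len(filtered) == 0
        assert report.initial == report.final == 0

    def test_unannotated_accessions_counted_not_extracellular(self, toy_matrix):
        matrix, gocc = toy_matrix
        gocc = dict(gocc)
        del gocc["P6"]
        filtered, report = filter_secretome(matrix, gocc)
        assert report.unannotated == 1
        assert len(filtered) == 0  # the lone survivor relied on P6's annotation

    def test_detection_rule_both_clones_of_one_ko(self, toy_design):
        """A protein seen once per clone (but <2 WT) passes; once in one clone fails."""
        cols = list(toy_design.all_samples)
        rows = {
            "both_clones": {
                "WT_1": 1e6, "KO_C1_1": 1e6, "KO_C2_1": 1e6,
            },
            "one_clone": {"WT_1": 1e6, "KO_C1_1": 1e6, "KO_C1_2": 1e6},
        }
        intens = pd.DataFrame(
            [[rows[r].get(c, np.nan) for c in cols] for r in rows],
            index=list(rows), columns=cols,
        )
        meta = pd.DataFrame(
            {
                "members": [("A1",), ("A2",)],
                "peptides": [5, 5],
                "contaminant": False, "reverse": False, "only_by_site": False,
            },
            index=intens.index,
        )
        gocc = {"A1": frozenset({"extracellular region"}),
                "A2": frozenset({"extracellular region"})}
        filtered, _ = filter_secretome(LfqMatrix(intens, meta, toy_design), gocc)
        assert list(filtered.group_ids) == ["both_clones"]


class TestImputation:
    def _matrix_with_missing(self, n_missing, observed=(23.0, 25.0, 27.0)):
        col = list(2.0 ** np.array(observed)) + [np.nan] * n_missing
        return pd.DataFrame({"s1": col})

    def test_moments_match_downshifted_normal(self):
        """10^4 draws into a column with observed mean 25, sd 2 (log2)."""
        df = self._matrix_with_missing(10_000)
        out = log2_and_impute(df, ImputeConfig(seed=11))
        draws = out["s1"].iloc[3:]
        assert draws.mean() == pytest.approx(25 - 1.8 * 2, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(0.3 * 2, abs=0.02)

    def test_complete_column_returned_unchanged(self):
        df = self._matrix_with_missing(0)
        out = log2_and_impute(df, ImputeConfig(seed=1))
        assert np.allclose(out["s1"], np.log2(df["s1"]))

    def test_same_seed_reproduces_identical_matrix(self):
        df = self._matrix_with_missing(50)
        a = log2_and_impute(df, ImputeConfig(seed=42))
        b = log2_and_impute(df, ImputeConfig(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = log2_and_impute(df, ImputeConfig(seed=43))
        assert not a.equals(c)

    def test_observed_values_never_touched(self):
        df = self._matrix_with_missing(20)
        out = log2_and_impute(df, ImputeConfig(seed=2))
        assert np.allclose(out["s1"].iloc[:3], [23.0, 25.0, 27.0])

    def test_underobserved_column_error_names_it(self):
        df = pd.DataFrame({"good": [1e6, 2e6, 3e6], "bad": [1e6, np.nan, np.nan]})
        with pytest.raises(ValueError, match="'bad'"):
            log2_and_impute(df, ImputeConfig())

    def test_zero_intensities_treated_as_missing(self):
        df = pd.DataFrame({"s": [8.0, 32.0, 128.0, 0.0, 0.0, 0.0]})
        out = log2_and_impute(df, ImputeConfig(seed=3))
        assert out["s"].notna().all()
        assert list(out["s"].iloc[:3]) == [3.0, 5.0, 7.0]


def oracle_student_t(a, b):
    """Equal-variance two-sample t and two-sided p via the incomplete beta."""
    na, nb = len(a), len(b)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = betainc(df / 2, 0.5, df / (df + t * t))
    return t, p


class TestDifferential:
    def test_hand_computed_3v6_matches_t_cdf_oracle(self):
        wt = [25.1, 24.8, 25.3]
        ko = [23.9, 24.2, 23.5, 24.0, 23.8, 24.4]
        df = pd.DataFrame(
            [wt + ko], columns=[f"w{i}" for i in range(3)] + [f"k{i}" for i in range(6)]
        )
        res = differential_test(df, [f"w{i}" for i in range(3)], [f"k{i}" for i in range(6)])
        t_o, p_o = oracle_student_t(ko, wt)
        assert res.table["t"].iloc[0] == pytest.approx(t_o, abs=1e-8)
        assert res.table["p"].iloc[0] == pytest.approx(p_o, abs=1e-8)
        assert res.table["log2_fc"].iloc[0] == pytest.approx(np.mean(ko) - np.mean(wt))
        assert bool(res.table["significant"].iloc[0])

    def test_random_rows_match_oracle(self, rng):
        wt_cols = [f"w{i}" for i in range(3)]
        ko_cols = [f"k{i}" for i in range(6)]
        data = rng.normal(25, 2, size=(50, 9))
        df = pd.DataFrame(data, columns=wt_cols + ko_cols)
        res = differential_test(df, wt_cols, ko_cols)
        for i in range(50):
            t_o, p_o = oracle_student_t(data[i, 3:], data[i, :3])
            assert res.table["t"].iloc[i] == pytest.approx(t_o, abs=1e-8)
            assert res.table["p"].iloc[i] == pytest.approx(p_o, abs=1e-8)

    def test_identical_groups_are_null(self):
        df = pd.DataFrame([[5.0] * 6], columns=list("abcdef"))
        res = differential_test(df, ["a", "b", "c"], ["d", "e", "f"])
        row = res.table.iloc[0]
        assert row["log2_fc"] == 0.0
        assert row["p"] == 1.0
        assert not row["significant"]

    def test_zero_variance_unequal_means_is_extreme_not_nan(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0, 7.0, 7.0, 7.0]], columns=list("abcdef"))
        res = differential_test(df, ["a", "b", "c"], ["d", "e", "f"])
        assert 0 < res.table["p"].iloc[0] <= 1e-300
        assert res.table["log2_fc"].iloc[0] == 2.0

    def test_requires_two_samples_per_side(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        with pytest.raises(ValueError):
            differential_test(df, ["a"], ["b", "c"])


class TestPerCloneFoldChanges:
    clones = {"KO": {"C1": ["c1a", "c1b"], "C2": ["c2a", "c2b"]}}

    def test_samples_at_wt_mean_have_zero_fold_change(self):
        df = pd.DataFrame(
            [[24.0, 26.0, 25.0, 25.0, 25.0, 25.0]],
            columns=["w1", "w2", "c1a", "c1b", "c2a", "c2b"],
        )
        fc = per_clone_fold_changes(df, ["w1", "w2"], self.clones)
        assert np.allclose(fc[["c1a", "c1b", "c2a", "c2b", "KO_mean"]], 0.0)

    def test_toy_arithmetic(self):
        df = pd.DataFrame(
            [[24.0, 26.0, 24.0, 26.0, 23.0, 27.0]],
            columns=["w1", "w2", "c1a", "c1b", "c2a", "c2b"],
        )
        fc = per_clone_fold_changes(df, ["w1", "w2"], self.clones)
        assert fc["c1a"].iloc[0] == -1.0
        assert fc["c2b"].iloc[0] == 2.0
        assert fc["KO_mean"].iloc[0] == pytest.approx((-1 + 1 - 2 + 2) / 4)

    def test_mean_of_fold_changes_equals_fold_change_of_means(self, rng):
        cols = ["w1", "w2", "w3", "c1a", "c1b", "c2a", "c2b"]
        df = pd.DataFrame(rng.normal(25, 2, size=(30, 7)), columns=cols)
        fc = per_clone_fold_changes(df, ["w1", "w2", "w3"], self.clones)
        direct = df[["c1a", "c1b", "c2a", "c2b"]].mean(axis=1) - df[
            ["w1", "w2", "w3"]
        ].mean(axis=1)
        assert np.allclose(fc["KO_mean"], direct)
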