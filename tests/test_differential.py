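"""Differential statistics: pooled-variance t, BH step-up, replicate QC,
significant-set overlap, hierarchical clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import footprintnet as fn

from conftest import SIX, make_matrix


def pooled_t_oracle(a, b):
    """Textbook two-sample equal-variance t (independent of the implementation)."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df


def bh_oracle(pvals):
    """Direct step-up computation: p_(i) * m / i with running minimum from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestDifferentialStats:
    def _matrix(self, treated, control):
        return make_matrix({"F": list(treated) + list(control)}, SIX)

    def test_identical_groups_give_null_result(self):
        d = fn.differential_stats(self._matrix([1, 2, 3], [1, 2, 3]),
                                  ("ITD-JMD.treated", "ITD-JMD.control"))
        row = d.table.loc["F"]
        assert row["log2fc"] == 0 and row["t_stat"] == 0 and row["p_value"] == 1

    def test_worked_example_matches_pooled_variance_formula(self):
        d = fn.differential_stats(self._matrix([11.0, 11.2, 11.4], [10.0, 10.2, 10.4]),
                                  ("ITD-JMD.treated", "ITD-JMD.control"))
        row = d.table.loc["F"]
        assert row["log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert row["t_stat"] == pytest.approx(6.123724356957945, abs=1e-10)
        assert row["df"] == 4

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(10, 1, 3)
            b = rng.normal(10, 1, 3)
            d = fn.differential_stats(self._matrix(a, b),
                                      ("ITD-JMD.treated", "ITD-JMD.control"))
            t_exp, df_exp = pooled_t_oracle(a, b)
            row = d.table.loc["F"]
            assert row["t_stat"] == pytest.approx(t_exp, abs=1e-10)
            assert row["df"] == df_exp
            assert row["p_value"] == pytest.approx(
                2 * stats.t.sf(abs(t_exp), df_exp), abs=1e-10)

    def test_agrees_with_scipy_ttest(self):
        rng = np.random.default_rng(1)
        vals = {f"F{i}": rng.normal(20, 1, 6) for i in range(50)}
        m = make_matrix(vals, SIX)
        d = fn.differential_stats(m, ("ITD-JMD.treated", "ITD-JMD.control"))
        for f, row in d.table.iterrows():
            res = stats.ttest_ind(vals[f][:3], vals[f][3:], equal_var=True)
            assert row["t_stat"] == pytest.approx(res.statistic, abs=1e-10)
            assert row["p_value"] == pytest.approx(res.pvalue, abs=1e-10)

    def test_significance_flag_follows_fdr_threshold(self):
        rng = np.random.default_rng(2)
        vals = {f"N{i}": rng.normal(20, 0.3, 6) for i in range(40)}
        vals.update({f"S{i}": np.r_[rng.normal(23, 0.3, 3), rng.normal(20, 0.3, 3)]
                     for i in range(10)})
        d = fn.differential_stats(make_matrix(vals, SIX),
                                  ("ITD-JMD.treated", "ITD-JMD.control"),
                                  fdr_threshold=0.1)
        assert (d.table["significant"] == (d.table["fdr"] < 0.1)).all()
        assert d.significant_features() >= {f"S{i}" for i in range(10)}

    def test_features_with_too_few_complete_values_are_excluded(self):
        m = make_matrix({"OK": [1, 2, 3, 4, 5, 6],
                         "BAD": [1, np.nan, np.nan, 4, 5, 6]}, SIX)
        d = fn.differential_stats(m, ("ITD-JMD.treated", "ITD-JMD.control"))
        assert "BAD" in d.excluded and "BAD" not in d.table.index

    def test_class_i_filter_applies_to_phospho_matrices(self):
        m = make_matrix({"A_S1": [1, 2, 3, 4, 5, 6], "B_T2": [1, 2, 3, 4, 5, 6]},
                        SIX, kind="phospho",
                        loc_prob={"A_S1": 0.95, "B_T2": 0.5})
        d = fn.differential_stats(m, ("ITD-JMD.treated", "ITD-JMD.control"))
        assert list(d.table.index) == ["A_S1"] and d.n_loc_filtered == 1

    def test_missing_contrast_condition_raises(self):
        m = make_matrix({"F": [1, 2, 3, 4, 5, 6]}, SIX)
        with pytest.raises(ValueError, match="ITD-TKD"):
            fn.differential_stats(m, ("ITD-TKD.treated", "ITD-JMD.control"))

    def test_sample_order_permutation_changes_nothing(self):
        rng = np.random.default_rng(3)
        vals = {f"F{i}": rng.normal(20, 1, 6) for i in range(20)}
        m1 = make_matrix(vals, SIX)
        perm = [SIX[i] for i in rng.permutation(6)]
        m2 = fn.OmicsMatrix(m1.values[perm], "proteome")
        d1 = fn.differential_stats(m1, ("ITD-JMD.treated", "ITD-JMD.control"))
        d2 = fn.differential_stats(m2, ("ITD-JMD.treated", "ITD-JMD.control"))
        pd.testing.assert_frame_equal(d1.table, d2.table)

    def test_type_i_error_under_global_null(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 0.5, size=(10_000, 6))
        df = pd.DataFrame(vals, index=[f"F{i:05d}" for i in range(10_000)], columns=SIX)
        d = fn.differential_stats(fn.OmicsMatrix(df, "proteome"),
                                  ("ITD-JMD.treated", "ITD-JMD.control"))
        frac = float((d.table["p_value"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.02


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert fn.bh_adjust([0.05]) == pytest.approx([0.05])

    def test_worked_step_up_example(self):
        assert fn.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_ones(self):
        assert fn.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fn.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, pvals):
        assert fn.bh_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)

    def test_matches_oracle_on_100_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 50)))
            assert fn.bh_adjust(p) == pytest.approx(bh_oracle(list(p)), abs=1e-10)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        assert (fn.bh_adjust(p) >= p - 1e-15).all()


class TestReplicateCorrelation:
    def test_self_and_perfect_linear_correlation(self):
        m = make_matrix({"A": [1, 2, 1, 2, 1, 2], "B": [2, 4, 2, 4, 2, 4],
                         "C": [3, 6, 3, 6, 3, 6]}, SIX)
        corr, _ = fn.replicate_correlation(m)
        for c in SIX:
            assert corr.loc[c, c] == pytest.approx(1.0)
        assert corr.loc[SIX[0], SIX[1]] == pytest.approx(1.0)  # proportional columns

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(7)
        vals = {f"F{i}": rng.normal(0, 1, 6) for i in range(30)}
        m = make_matrix(vals, SIX)
        corr, _ = fn.replicate_correlation(m)
        x = m.values[SIX[0]].to_numpy()
        y = m.values[SIX[1]].to_numpy()
        r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert corr.loc[SIX[0], SIX[1]] == pytest.approx(r, abs=1e-12)

    def test_undefined_pair_flagged_in_qc(self):
        vals = {"A": [1, np.nan, 3, 4, 5, 6], "B": [np.nan, 2, 3, 4, 5, 6]}
        m = make_matrix(vals, SIX)
        corr, report = fn.replicate_correlation(m)
        assert np.isnan(corr.loc[SIX[0], SIX[1]])
        reasons = {tuple(w["pair"]): w["reason"] for w in report["warnings"]}
        assert reasons[(SIX[0], SIX[1])] == "undefined"

    def test_low_correlation_warned_below_floor(self):
        rng = np.random.default_rng(8)
        vals = {f"F{i}": rng.normal(0, 1, 6) for i in range(40)}
        m = make_matrix(vals, SIX)
        _, report = fn.replicate_correlation(m, floor=0.75)
        assert report["floor"] == 0.75 and len(report["warnings"]) > 0


class TestCompareSignificantSets:
    def _table(self, sig, nonsig):
        idx = list(sig) + list(nonsig)
        df = pd.DataFrame({"log2fc": 1.0, "t_stat": 1.0, "df": 4, "p_value": 0.5,
                           "fdr": [0.01] * len(sig) + [0.9] * len(nonsig),
                           "significant": [True] * len(sig) + [False] * len(nonsig),
                           "n_treated": 3, "n_control": 3},
                          index=pd.Index(idx, name="feature"))
        return fn.DifferentialTable(df, ("t", "c"), 0.1)

    def test_identical_sets_intersection_equals_union(self):
        t = self._table(["a", "b"], ["x"])
        out = fn.compare_significant_sets({"J": t, "T": t})
        assert out["intersection"] == out["union"] == ["a", "b"]

    def test_disjoint_sets(self):
        out = fn.compare_significant_sets(
            {"J": self._table(["a", "b"], []), "T": self._table(["c"], [])})
        assert out["intersection_count"] == 0 and out["union_count"] == 3
        assert out["only"]["J"] == ["a", "b"] and out["only"]["T"] == ["c"]

    def test_random_sets_match_naive_set_arithmetic(self):
        rng = np.random.default_rng(9)
        universe = [f"f{i}" for i in range(40)]
        picks = {ctx: {f for f in universe if rng.random() < 0.4}
                 for ctx in ("A", "B", "C")}
        tables = {ctx: self._table(sorted(s), sorted(set(universe) - s))
                  for ctx, s in picks.items()}
        out = fn.compare_significant_sets(tables)
        assert set(out["intersection"]) == picks["A"] & picks["B"] & picks["C"]
        assert set(out["union"]) == picks["A"] | picks["B"] | picks["C"]

    def test_needs_two_contexts(self):
        with pytest.raises(ValueError):
            fn.compare_significant_sets({"J": self._table(["a"], [])})


class TestClusterFeatures:
    def test_k_one_puts_everything_in_cluster_one(self):
        rng = np.random.default_rng(10)
        m = make_matrix({f"F{i}": rng.normal(0, 1, 6) for i in range(5)}, SIX)
        assign = fn.cluster_features(m, k=1)
        assert set(assign) == {1}

    def test_perfectly_anticorrelated_groups_recovered(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        vals = {"U1": base, "U2": 2 * base + 1, "U3": base - 4,
                "D1": -base, "D2": -3 * base + 2, "D3": 5 - base}
        assign = fn.cluster_features(make_matrix(vals, SIX), k=2)
        up = {f for f in assign.index if assign[f] == assign["U1"]}
        assert up == {"U1", "U2", "U3"}

    def test_invalid_k_raises(self):
        m = make_matrix({"A": [1] * 6, "B": [2] * 6}, SIX)
        with pytest.raises(ValueError):
            fn.cluster_features(m, k=0)
        with pytest.raises(ValueError):
            fn.cluster_features(m, k=3)

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(11)
        m = make_matrix({f"F{i}": rng.normal(0, 1, 6) for i in range(30)}, SIX)
        a1 = fn.cluster_features(m, k=4)
        a2 = fn.cluster_features(m, k=4)
        assert a1.equals(a2)
        assert set(a1.unique()) == {1, 2, 3, 4}
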