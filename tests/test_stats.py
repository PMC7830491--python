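"""Rank tests, BH adjustment, ANOVA, PERMANOVA and nMDS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from csiatrace.stats import (
    bh_adjust,
    kruskal_wallis,
    nmds,
    pairwise_wilcoxon_bh,
    permanova,
    two_way_anova_tukey,
    variance_checks,
)


class TestKruskalWallis:
    def test_hand_rank_computation(self):
        # three tie-free groups {1,2,3}, {4,5,6}, {7,8,9}: H = 7.2
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(values, groups)
        assert res.statistic == pytest.approx(7.2, abs=1e-10)

    def test_identical_groups_are_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = kruskal_wallis([5.0, 5.0, 5.0, 5.0], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_p_values_are_uniform(self):
        # identical-distribution groups: p should be U(0,1) over simulations
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(1000):
            values = rng.normal(size=24)
            groups = np.repeat(["a", "b", "c"], 8)
            pvals.append(kruskal_wallis(values, groups).p_value)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04], abs=1e-12)

    def test_single_test_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037], abs=1e-15)

    def test_identical_ps_are_a_fixed_point(self):
        assert bh_adjust([0.05] * 7) == pytest.approx([0.05] * 7, abs=1e-15)

    def test_monotone_capped_and_matches_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        ref = multipletests(p, method="fdr_bh")[1]
        assert adj == pytest.approx(ref, abs=1e-12)


class TestPairwiseWilcoxon:
    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(6, 1, 8), rng.normal(12, 1, 8)])
        groups = np.repeat(["a", "b", "c"], 8)
        results = pairwise_wilcoxon_bh(values, groups)
        assert len(results) == 3
        assert all(r.p_adjusted is not None and r.p_adjusted < 0.05 for r in results)
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in results)

    def test_small_group_skipped_with_warning(self):
        values = [1.0, 2.0, 3.0, 4.0, 9.0]
        groups = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="skipped"):
            results = pairwise_wilcoxon_bh(values, groups)
        assert {r.groups for r in results} == {("a", "b")}


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "y": [3.0] * 8,
                "feeding": ["auto", "auto", "hetero", "hetero"] * 2,
                "fraction": ["host", "symbiont"] * 4,
            }
        )
        res = two_way_anova_tukey(df, "y", "feeding", "fraction")
        assert res.table.loc["feeding", "F"] == 0.0
        assert res.table.loc["fraction", "F"] == 0.0

    def test_balanced_toy_sums_of_squares_by_hand(self):
        # additive means, zero noise: y = a_i + b_j with a = (0, 4), b = (0, 2),
        # two replicates per cell; factor SS are n * sum of squared effect
        # deviations: SS_A = 8*(2^2)/... computed directly below
        rows = []
        for a, av in (("a1", 0.0), ("a2", 4.0)):
            for b, bv in (("b1", 0.0), ("b2", 2.0)):
                for _ in range(2):
                    rows.append({"y": av + bv, "A": a, "B": b})
        df = pd.DataFrame(rows)
        res = two_way_anova_tukey(df, "y", "A", "B")
        # grand mean 3; A means (1, 5) -> SS_A = 4*((1-3)^2 + (5-3)^2) = 32
        # B means (2, 4) -> SS_B = 4*1 + 4*1 = 8; residual 0
        assert res.table.loc["A", "sum_sq"] == pytest.approx(32.0, abs=1e-10)
        assert res.table.loc["B", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_sequential_ss_match_projection_oracle(self):
        # independent oracle: explicit sequential projections in numpy
        rng = np.random.default_rng(42)
        n = 30
        A = rng.choice(["a1", "a2", "a3"], n)
        B = rng.choice(["b1", "b2"], n)
        y = rng.normal(size=n) + (A == "a2") * 1.5 + (B == "b2") * 0.7

        def hat(X):
            q, _ = np.linalg.qr(X)
            return q @ q.T

        ones = np.ones((n, 1))
        Xa = np.column_stack([ones] + [(A == lv).astype(float) for lv in ["a2", "a3"]])
        Xab = np.column_stack([Xa, (B == "b2").astype(float)])
        ss_a = y @ (hat(Xa) - hat(ones)) @ y
        ss_b = y @ (hat(Xab) - hat(Xa)) @ y
        ss_res = y @ (np.eye(n) - hat(Xab)) @ y

        df = pd.DataFrame({"y": y, "A": A, "B": B})
        res = two_way_anova_tukey(df, "y", "A", "B")
        assert res.table.loc["A", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
        assert res.table.loc["B", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-8)
        assert "A" in res.tukey and "B" in res.tukey

    def test_empty_cell_is_an_error(self):
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0],
                "A": ["a1", "a1", "a2", "a2"],
                "B": ["b1", "b2", "b1", "b1"],
            }
        )
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova_tukey(df, "y", "A", "B")


def _oneway_pseudo_f(x, labels):
    """Independent one-way pseudo-F from pairwise distances only."""
    x = np.asarray(x, dtype=float).reshape(len(x), -1)
    labels = np.asarray(labels)
    n = len(x)
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_exhaustive_enumeration_oracle_separated_groups(self):
        # {0,0,0} vs {10,10,10} in 1-D: only the 2 of C(6,3)=20 assignments
        # that reproduce the split achieve the (infinite) pseudo-F, so the
        # exact p is 2/20 = 0.1
        X = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.0]])
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(X, {"grp": labels}, permutations="exact")
        assert res.p_value["grp"] == pytest.approx(0.1, abs=1e-12)
        # partition matches direct computation: SS_among = 3*3*100/6 = 150? no:
        # total SS = sum of squared deviations from centroid = 6 * 25 = 150,
        # all of it among groups
        assert res.sum_sq["Total"] == pytest.approx(150.0, abs=1e-9)
        assert res.sum_sq["grp"] == pytest.approx(150.0, abs=1e-9)
        assert res.sum_sq["Residuals"] == pytest.approx(0.0, abs=1e-9)

    def test_pseudo_f_and_p_match_enumeration_on_noisy_data(self):
        rng = np.random.default_rng(7)
        X = np.concatenate([rng.normal(0, 1, (3, 1)), rng.normal(2, 1, (3, 1))])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(X, {"grp": labels}, permutations="exact")
        f_oracle = _oneway_pseudo_f(X, labels)
        assert res.pseudo_f["grp"] == pytest.approx(f_oracle, rel=1e-9)
        # oracle p: enumerate all 20 label assignments
        count = 0
        idx = range(6)
        for comb in itertools.combinations(idx, 3):
            lab = np.array(["b"] * 6)
            lab[list(comb)] = "a"
            if _oneway_pseudo_f(X, lab) >= f_oracle - 1e-12:
                count += 1
        assert res.p_value["grp"] == pytest.approx(count / 20.0, abs=1e-12)

    def test_agrees_with_skbio_reference(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(19)
        X = rng.normal(size=(12, 4))
        X[6:] += 1.0
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(X, {"grp": labels}, n_perm=99, seed=1)
        dm = DistanceMatrix(squareform(pdist(X)))
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f["grp"] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_two_factor_partition_sums_to_total(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(24, 5))
        factors = pd.DataFrame(
            {
                "treatment": np.repeat(["auto", "hetero"], 12),
                "compartment": np.tile(np.repeat(["host", "symb"], 6), 2),
            }
        )
        res = permanova(X, factors, n_perm=99, seed=2)
        parts = res.sum_sq["treatment"] + res.sum_sq["compartment"] + res.sum_sq["Residuals"]
        assert parts == pytest.approx(res.sum_sq["Total"], abs=1e-9)
        assert res.df["treatment"] + res.df["compartment"] + res.df["Residuals"] == res.df["Total"]

    def test_f_invariant_to_within_group_relabeling(self):
        rng = np.random.default_rng(31)
        base = rng.normal(size=(4, 3))
        X = np.vstack([base, base])  # duplicated coordinates
        labels = np.array(["g1", "g1", "g2", "g2"] * 2)
        res1 = permanova(X, {"grp": labels}, n_perm=99, seed=3)
        # swap samples within each group: F must be unchanged
        order = [1, 0, 3, 2, 5, 4, 7, 6]
        res2 = permanova(X[order], {"grp": labels[order]}, n_perm=99, seed=3)
        assert res1.pseudo_f["grp"] == pytest.approx(res2.pseudo_f["grp"], rel=1e-9)

    def test_low_n_perm_warns(self):
        X = np.random.default_rng(1).normal(size=(8, 2))
        with pytest.warns(UserWarning, match="coarse"):
            permanova(X, {"grp": ["a"] * 4 + ["b"] * 4}, n_perm=49, seed=1)


class TestNmds:
    def test_three_equidistant_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = nmds(D, seed=0, n_random_starts=4)
        assert res.stress < 1e-3
        # embedding is an equilateral triangle up to rigid motion
        from scipy.spatial.distance import pdist

        d = pdist(res.coordinates)
        assert np.ptp(d) / d.mean() < 0.01

    def test_planar_configuration_recovered(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        res = nmds(squareform(pdist(pts)), seed=1)
        assert res.stress < 0.01

    def test_more_iterations_never_increase_stress(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(9)
        D = squareform(pdist(rng.normal(size=(12, 6))))
        short = nmds(D, seed=4, n_random_starts=0, max_iter=2)
        long = nmds(D, seed=4, n_random_starts=0, max_iter=300)
        assert long.stress <= short.stress + 1e-12

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            nmds(D)


class TestVarianceChecks:
    def test_equal_variance_groups_pass(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, 60)
        groups = np.repeat(["a", "b", "c"], 20)
        res = variance_checks(values, groups)
        assert res["levene"].p_value > 0.01
        assert res["bartlett"].p_value > 0.01

    def test_hundredfold_variance_detected(self):
        rng = np.random.default_rng(13)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 10, 30)])
        groups = np.repeat(["a", "b"], 30)
        res = variance_checks(values, groups)
        assert res["levene"].p_value < 0.01

    def test_constant_data_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = variance_checks([1.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert res["levene"].note == "constant data"
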