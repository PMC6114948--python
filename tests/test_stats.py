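"""Rank statistics: Spearman p-values, bootstrap CIs, BH-FDR, Wilcoxon, Fisher,
local median curves, and the stratified / gene-wise / mutation-status screens."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from luscage.stats import (
    assign_age_groups,
    bh_fdr,
    bootstrap_rho_ci,
    fisher_exact,
    gene_wise_age_correlation,
    load_by_mutation_status,
    local_median_curve,
    spearman_rho,
    spearman_test,
    stratified_age_correlation,
    wilcoxon_rank_sum,
)


def exact_spearman_oracle(x, y):
    """Two-sided permutation p by full enumeration (tie-free small n)."""
    n = len(x)
    rho_obs = abs(spearman_rho(x, y))
    hits = total = 0
    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    for perm in itertools.permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        hits += abs(rho) >= rho_obs - 1e-12
        total += 1
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], ci=False)
        assert res.rho == pytest.approx(1.0)
        res = spearman_test([1, 2, 3, 4, 5], [10, 8, 6, 4, 2], ci=False)
        assert res.rho == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        res = spearman_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], ci=False)
        assert np.isnan(res.rho) and res.flag == "constant"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman_test(x, y, ci=False)
        trans = spearman_test(np.exp(x), y**3, ci=False)
        assert base.rho == pytest.approx(trans.rho)
        assert base.p_value == pytest.approx(trans.p_value)

    def test_pairwise_complete_observations(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [2, 4, 6, 8, 10, 3]
        res = spearman_test(x, y, ci=False)
        assert res.n == 5 and res.rho == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_n_matches_exact_permutation_oracle(self, seed):
        """n=7 tie-free: p within 0.005 of full 7! enumeration."""
        rng = np.random.default_rng(seed)
        x = rng.permutation(7).astype(float)
        y = rng.normal(size=7)
        res = spearman_test(x, y, ci=False)
        assert res.p_value == pytest.approx(exact_spearman_oracle(x, y), abs=0.005)

    def test_agrees_with_R_cor_test(self):
        """Frozen oracle values from R 4.3.3 cor.test(method='spearman'),
        which uses exact enumeration (n<=9) / AS 89 Edgeworth beyond."""
        res = spearman_test([1, 2, 3, 4, 5, 6, 7], [2, 1, 4, 3, 7, 5, 6], ci=False)
        assert res.rho == pytest.approx(0.8214285714)
        assert res.p_value == pytest.approx(0.0341269841, abs=1e-9)

        x12 = [3, 1, 4, 1.5, 5, 9, 2.6, 5.3, 5.8, 9.7, 9.3, 2.3]
        y12 = [2, 7, 1, 8, 2.8, 1.8, 2.84, 5.9, 4.5, 3.4, 5.6, 8.9]
        res = spearman_test(x12, y12, ci=False)
        assert res.rho == pytest.approx(-0.3846153846)
        assert res.p_value == pytest.approx(0.2183874269, abs=0.0025)

        rng = np.random.default_rng(2024)
        # frozen n=50 case: R reports p=0.2351441300 for these data
        x50 = [-0.626454, 0.183643, -0.835629, 1.595281, 0.329508, -0.820468,
               0.487429, 0.738325, 0.575781, -0.305388, 1.511781, 0.389843,
               -0.621241, -2.2147, 1.124931, -0.044934, -0.01619, 0.943836,
               0.821221, 0.593901, 0.918977, 0.782136, 0.074565, -1.989352,
               0.619826, -0.056129, -0.155796, -1.470752, -0.47815, 0.417942,
               1.35868, -0.102788, 0.387672, -0.053805, -1.37706, -0.414995,
               -0.39429, -0.059313, 1.100025, 0.763176, -0.164524, -0.253362,
               0.696963, 0.556663, -0.688756, -0.707495, 0.364582, 0.768533,
               -0.112346, 0.881108]
        y50 = [0.147524, -0.538569, 0.006868, -0.491251, 1.564827, 1.652213,
               -0.17225, -0.748805, 0.800032, -0.25721, 3.00633, 0.116697,
               0.441243, -0.857878, -0.293301, 0.170819, -1.811435, 1.843089,
               0.481742, 2.410172, 0.8431, -0.397092, 0.640552, -1.729838,
               -1.005703, 0.268995, -0.50561, -0.587196, -0.116919, -0.422344,
               -0.025197, -0.176294, 1.333156, -1.545089, 0.043122, 0.166953,
               0.905384, -0.327909, 0.810029, 0.572369, -0.608329, 1.106523,
               1.439188, 0.922879, 1.311331, 0.275488, -1.130759, -0.265852,
               -1.269551, -0.120958]
        res = spearman_test(x50, y50, ci=False)
        assert res.rho == pytest.approx(0.1707082833)
        assert res.p_value == pytest.approx(0.23514413, abs=0.002)


class TestBootstrapCI:
    def test_identical_vectors_degenerate_interval(self):
        x = np.arange(20.0)
        lo, hi = bootstrap_rho_ci(x, x, B=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert bootstrap_rho_ci(x, y, seed=7) == bootstrap_rho_ci(x, y, seed=7)
        assert bootstrap_rho_ci(x, y, seed=7) != bootstrap_rho_ci(x, y, seed=8)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        lo, hi = bootstrap_rho_ci(x, y, seed=3)
        assert lo <= spearman_rho(x, y) <= hi


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        np.testing.assert_allclose(q[order], bh_fdr(p[order]))
        assert np.all(q >= p)

    @pytest.mark.parametrize("alpha", [0.05, 0.2])
    def test_rejection_set_matches_step_up_oracle(self, alpha):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-4, 1, size=rng.integers(3, 40))
            q = bh_fdr(p)
            # brute-force BH step-up: largest k with p_(k) <= k/m * alpha
            srt = np.sort(p)
            m = p.size
            k = max((i + 1 for i in range(m) if srt[i] <= (i + 1) / m * alpha), default=0)
            rejected_oracle = set(np.where(p <= (srt[k - 1] if k else -1))[0])
            assert set(np.where(q <= alpha)[0]) == rejected_oracle

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestWilcoxon:
    def test_extreme_three_vs_three(self):
        """Fully separated 3-vs-3: exact two-sided p = 2/C(6,3) = 0.1."""
        _, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_all_tied_flagged_p_one(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_and_normal_approximation_agree_at_n20(self):
        """|p_exact - p_asymptotic| < 0.01 at n=20/20 (tie-free random data)."""
        rng = np.random.default_rng(4)
        worst = 0.0
        for _ in range(100):
            a = rng.normal(size=20)
            b = rng.normal(rng.uniform(0, 1), size=20)
            p_exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            p_norm = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            worst = max(worst, abs(p_exact - p_norm))
        assert worst < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    def test_no_association(self):
        assert fisher_exact([[3, 3], [3, 3]]) == pytest.approx(1.0)

    def test_zero_margin(self):
        assert fisher_exact([[10, 0], [10, 0]]) == pytest.approx(1.0)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestLocalMedianCurve:
    def test_constant_values_flat_zero_width(self):
        ages = np.linspace(40, 80, 50)
        curve = local_median_curve(ages, np.full(50, 7.0), B=100, seed=0)
        assert np.allclose(curve.median[~np.isnan(curve.median)], 7.0)
        assert np.allclose(curve.ci_low[~np.isnan(curve.ci_low)], 7.0)
        assert np.allclose(curve.ci_high[~np.isnan(curve.ci_high)], 7.0)

    def test_identity_values_hand_windowing(self):
        ages = np.array([40, 42, 47, 53, 55, 60, 66, 71, 75, 80], dtype=float)
        curve = local_median_curve(ages, ages, halfwidth=10, B=10, seed=0,
                                   grid=np.array([50.0]))
        in_window = ages[np.abs(ages - 50) <= 10]
        assert curve.median[0] == pytest.approx(np.median(in_window))

    def test_sparse_window_undefined(self):
        ages = np.array([40.0, 41.0, 42.0, 80.0])
        curve = local_median_curve(ages, ages, halfwidth=2, B=10, seed=0,
                                   grid=np.array([41.0, 60.0, 80.0]), min_n=3)
        assert not np.isnan(curve.median[0])
        assert np.isnan(curve.median[1]) and np.isnan(curve.median[2])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(40, 85, 60)
        vals = rng.normal(size=60)
        c1 = local_median_curve(ages, vals, B=100, seed=9)
        c2 = local_median_curve(ages, vals, B=100, seed=9)
        np.testing.assert_array_equal(c1.ci_low, c2.ci_low)


class TestStratified:
    def test_single_stratum_matches_global(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=40)
        ages = rng.uniform(40, 85, 40)
        table = stratified_age_correlation(values, ages, ["all"] * 40, B=50, seed=0)
        assert table.loc["global", "rho"] == pytest.approx(table.loc["all", "rho"])
        assert table.loc["global", "n"] == 40

    def test_opposite_sign_strata_recovered(self):
        rng = np.random.default_rng(7)
        n = 150
        ages = np.concatenate([rng.uniform(40, 85, n), rng.uniform(40, 85, n)])
        z = (ages - 62.5) / 13.0
        values = np.concatenate([
            0.5 * z[:n] + rng.normal(scale=np.sqrt(1 - 0.25), size=n),
            -0.5 * z[n:] + rng.normal(scale=np.sqrt(1 - 0.25), size=n),
        ])
        strata = ["pos"] * n + ["neg"] * n
        table = stratified_age_correlation(values, ages, strata, B=50, seed=1)
        assert table.loc["pos", "rho"] > 0.2
        assert table.loc["neg", "rho"] < -0.2

    def test_tiny_stratum_emitted_undefined(self):
        values = np.arange(10.0)
        ages = np.arange(10.0)
        strata = ["big"] * 8 + ["tiny"] * 2
        table = stratified_age_correlation(values, ages, strata, B=20, seed=0)
        assert np.isnan(table.loc["tiny", "rho"]) and table.loc["tiny", "n"] == 2

    def test_no_labels_is_error(self):
        with pytest.raises(ValueError, match="stratum"):
            stratified_age_correlation([1, 2, 3, 4], [1, 2, 3, 4], [np.nan] * 4)


class TestGeneWise:
    def test_age_tracking_gene_ranks_first(self):
        rng = np.random.default_rng(8)
        ages = pd.Series(rng.uniform(40, 85, 30), index=[f"P{i}" for i in range(30)])
        matrix = pd.DataFrame(
            rng.normal(size=(10, 30)), columns=ages.index,
            index=[f"G{i}" for i in range(10)],
        )
        matrix.loc["G0"] = ages.to_numpy()
        table = gene_wise_age_correlation(matrix, ages)
        assert table.loc["G0", "rho"] == pytest.approx(1.0)
        assert table["q_value"].idxmin() == "G0"

    def test_identical_rows_identical_stats(self):
        rng = np.random.default_rng(9)
        ages = pd.Series(rng.uniform(40, 85, 20), index=[f"P{i}" for i in range(20)])
        row = rng.poisson(2.0, size=20)
        matrix = pd.DataFrame([row, row], columns=ages.index, index=["G1", "G2"])
        table = gene_wise_age_correlation(matrix, ages)
        assert table.loc["G1", "rho"] == table.loc["G2", "rho"]
        assert table.loc["G1", "p_value"] == table.loc["G2", "p_value"]

    def test_constant_gene_flagged(self):
        ages = pd.Series([50.0, 60, 70, 80], index=list("abcd"))
        matrix = pd.DataFrame([[1, 1, 1, 1]], columns=ages.index, index=["G1"])
        table = gene_wise_age_correlation(matrix, ages)
        assert table.loc["G1", "flag"] == "constant"

    def test_null_genes_fdr_control_band(self):
        """500 permuted (null) genes: share with q <= 0.2 stays below 0.25."""
        rng = np.random.default_rng(10)
        n = 60
        ages = pd.Series(rng.uniform(40, 85, n), index=[f"P{i}" for i in range(n)])
        matrix = pd.DataFrame(
            rng.normal(size=(500, n)), columns=ages.index,
            index=[f"G{i}" for i in range(500)],
        )
        table = gene_wise_age_correlation(matrix, ages)
        assert (table["q_value"] <= 0.2).mean() <= 0.25


class TestAgeGroups:
    def test_left_open_right_closed_boundaries(self):
        groups = assign_age_groups([45, 50, 50.5, 60, 61, 80, 81])
        assert list(groups.astype(str)) == [
            "<=50", "<=50", "50-60", "50-60", "60-70", "70-80", ">80"
        ]


class TestLoadByMutationStatus:
    @staticmethod
    def _inputs(rng, effect=0.0):
        patients = [f"P{i}" for i in range(60)]
        loads = pd.Series(rng.normal(10, 2, 60), index=patients)
        status = pd.DataFrame(
            rng.random((3, 60)) < 0.4, index=["G1", "G2", "G3"], columns=patients
        )
        loads[status.loc["G1"]] += effect
        groups = pd.Series(["<=60"] * 30 + [">60"] * 30, index=patients)
        return loads, status, groups

    def test_identical_arms_p_one(self):
        rng = np.random.default_rng(11)
        loads, status, groups = self._inputs(rng)
        loads[:] = 5.0
        table, _ = load_by_mutation_status(loads, status, groups)
        assert (table["p_value"].dropna() == 1.0).all()

    def test_gene_never_mutated_flagged(self):
        rng = np.random.default_rng(12)
        loads, status, groups = self._inputs(rng)
        status.loc["G3"] = False
        table, _ = load_by_mutation_status(loads, status, groups)
        assert (table.loc[table["gene"] == "G3", "flag"] == "empty-arm").all()

    def test_fraction_any_mutated(self):
        rng = np.random.default_rng(13)
        loads, status, groups = self._inputs(rng)
        _, fractions = load_by_mutation_status(loads, status, groups)
        members = groups[groups == "<=60"].index
        assert fractions["<=60"] == pytest.approx(status[members].any(axis=0).mean())

    def test_mutator_effect_detected(self):
        """+2 sd load in carriers of one gene: p < 0.05 in >= 80% of seeded reps."""
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            loads, status, groups = self._inputs(rng, effect=4.0)  # 2 sd of 2
            table, _ = load_by_mutation_status(
                loads, status, pd.Series(["all"] * 60, index=loads.index)
            )
            p = table.loc[table["gene"] == "G1", "p_value"].iloc[0]
            hits += p < 0.05
        assert hits / reps >= 0.8
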