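"""Statistical battery: oracles, degenerate cases, invariances, calibration."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

import lenscurve as lc
from lenscurve.battery import DEMANDS


def wilcoxon_enumeration_p(d):
    """Oracle: exact two-sided signed-rank p by enumerating all 2^n sign
    assignments (zeros dropped, mid-ranks for ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    sums = np.asarray(sums)
    total = sums.size
    p_le = np.mean(sums <= w_obs + 1e-12)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPearson:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = lc.pearson_with_regression(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.extras["slope"] == pytest.approx(2.0)
        assert res.extras["intercept"] == pytest.approx(1.0)

    def test_r_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = lc.pearson_with_regression(x, y)
        r_direct = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
        assert res.statistic == pytest.approx(r_direct, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lc.pearson_with_regression(np.ones(5), np.arange(5.0))

    def test_phantom_age_aa_correlation_is_strongly_negative(self, small_cohort):
        meta = small_cohort.metadata
        res = lc.pearson_with_regression(meta["age"], meta["AA_D"])
        assert res.statistic <= -0.6


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        a = np.arange(8.0)
        res = lc.wilcoxon_paired(a, a)
        assert res.p_value == 1.0 and res.extras["degenerate"]

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        res = lc.wilcoxon_paired(a, b)
        assert res.extras["method"] == "exact"
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(a - b), abs=1e-12)

    def test_exact_p_with_ties_matches_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = np.array([0.0, 1.0, 1.0, 5.0, 4.0, 4.0, 9.0])  # tied |differences|
        res = lc.wilcoxon_paired(a, b)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(a - b), abs=1e-12)

    def test_zero_differences_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 2.0, 1.0])
        res = lc.wilcoxon_paired(a, b)
        assert res.n == 2

    def test_exact_and_normal_agree_at_boundary(self):
        # the two p-value routes must agree within 0.01 at n = 25
        rng = np.random.default_rng(123)
        for _ in range(20):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            p_exact = lc.wilcoxon_paired(a, b).p_value
            p_norm = lc.wilcoxon_paired(a, b, exact_max_n=0).p_value
            assert abs(p_exact - p_norm) <= 0.01

    def test_matches_scipy_normal_approximation_large_n(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=60)
        b = a + rng.normal(0.2, 1.0, size=60)
        ours = lc.wilcoxon_paired(a, b)
        ref = sps.wilcoxon(a, b, correction=True, method="approx")
        assert ours.extras["method"] == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-8)


class TestKruskal:
    def test_identical_groups_degenerate(self):
        g = [np.ones(4), np.ones(5), np.ones(3)]
        res = lc.kruskal_wallis(g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_small_instance_matches_hand_rank_computation(self):
        groups = [[1.0, 3.0], [2.0, 5.0, 6.0], [4.0, 7.0]]
        # pooled ranks are 1..7 with no ties: H by the textbook formula
        rank_sums = {0: 1 + 3, 1: 2 + 5 + 6, 2: 4 + 7}
        n = 7
        h_oracle = 12 / (n * (n + 1)) * sum(
            rank_sums[i] ** 2 / len(groups[i]) for i in range(3)
        ) - 3 * (n + 1)
        res = lc.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h_oracle, abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            lc.kruskal_wallis([[1.0, 2.0, 3.0]])


class TestFriedman:
    def test_constant_blocks_degenerate(self):
        m = np.tile([2.0], (5, 4))
        res = lc.friedman_repeated(m)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_small_instance_matches_explicit_rank_arithmetic(self):
        m = np.array(
            [[1.0, 2.0, 3.0],
             [2.0, 1.0, 3.0],
             [1.0, 3.0, 2.0],
             [1.0, 2.0, 3.0],
             [2.0, 3.0, 1.0]]
        )
        # within-block ranks equal the values themselves here
        rank_sums = m.sum(axis=0)
        b, k = m.shape
        chi_oracle = 12 / (b * k * (k + 1)) * (rank_sums**2).sum() - 3 * b * (k + 1)
        res = lc.friedman_repeated(m)
        assert res.statistic == pytest.approx(chi_oracle, abs=1e-12)
        ref_stat, ref_p = sps.friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(ref_stat, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_incomplete_blocks_dropped_listwise(self):
        m = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0], [3.0, 2.0, 1.0]])
        res = lc.friedman_repeated(m)
        assert res.n == 2

    def test_too_few_complete_blocks_rejected(self):
        with pytest.raises(ValueError):
            lc.friedman_repeated(np.array([[1.0, 2.0], [np.nan, 1.0]]))


class TestBonferroni:
    def test_six_contrast_threshold(self):
        policy = lc.CorrectionPolicy(0.05, 6)
        assert round(policy.threshold, 4) == 0.0083

    def test_single_contrast_threshold(self):
        assert lc.CorrectionPolicy(0.05, 1).threshold == pytest.approx(0.05)

    def test_boundary_p_is_not_significant(self):
        policy = lc.CorrectionPolicy(0.05, 6)
        out = lc.bonferroni(policy, {"c": policy.threshold})
        assert out["c"][1] is False

    def test_below_threshold_is_significant(self):
        out = lc.bonferroni(lc.CorrectionPolicy(0.05, 6), {"c": 0.008})
        assert out["c"][1] is True


class TestPermutationInvariance:
    def test_kruskal_group_relabeling(self):
        rng = np.random.default_rng(31)
        groups = [rng.normal(size=n) for n in (5, 8, 6)]
        h0 = lc.kruskal_wallis(groups).statistic
        h1 = lc.kruskal_wallis([groups[2], groups[0], groups[1]]).statistic
        assert h0 == pytest.approx(h1, abs=1e-12)

    def test_friedman_condition_relabeling(self):
        rng = np.random.default_rng(32)
        m = rng.normal(size=(10, 4))
        s0 = lc.friedman_repeated(m).statistic
        s1 = lc.friedman_repeated(m[:, [2, 0, 3, 1]]).statistic
        assert s0 == pytest.approx(s1, abs=1e-12)

    def test_wilcoxon_antisymmetry(self):
        rng = np.random.default_rng(33)
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert (
            lc.wilcoxon_paired(a, b).p_value
            == pytest.approx(lc.wilcoxon_paired(b, a).p_value, abs=1e-12)
        )


class TestFullBattery:
    def test_report_shapes(self, small_results):
        rep = small_results.report
        assert list(rep.wilcoxon_meridians.columns) == list(DEMANDS)
        assert set(rep.wilcoxon_meridians.index) == {"TG", "G1", "G2", "G3", "G4", "G5"}
        assert rep.kruskal_age_groups.shape == (2, 4)
        assert rep.friedman_demands.shape == (6, 2)
        for (g, s), pairs in rep.friedman_posthoc.items():
            assert len(pairs) == 6  # C(4,2) demand contrasts

    def test_all_p_values_valid(self, small_results):
        p = small_results.report.cell_p_values()
        assert np.all((p >= 0) & (p <= 1))

    def test_insufficient_group_marked_not_imputed(self, small_cohort):
        table = lc.build_cohort_table(small_cohort.eyes, small_cohort.metadata)
        # restrict to one subject: every grouped test is underpowered
        solo = table[table["subject_id"] == table["subject_id"].iloc[0]]
        rep = lc.run_full_battery(solo)
        assert rep.friedman_demands.isna().all().all()
        assert all(
            isinstance(v, str) and v.startswith("NA")
            for v in rep.pd_friedman.values()
        )

    def test_report_serialisation(self, small_results, tmp_path):
        import json

        path = tmp_path / "battery.json"
        small_results.report.to_json(path)
        data = json.loads(path.read_text())
        assert data["bonferroni_threshold"] == 0.0083
        assert "wilcoxon_meridians" in data and "correlations" in data
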