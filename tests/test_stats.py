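import itertools
import math

import numpy as np
import pytest
from scipy.stats import rankdata

from tcrdyn.stats import (
    bh_adjust,
    km_logrank,
    response_summary,
    shapiro_gate,
    spearman_trend,
    wilcoxon_rank_sum,
)

from conftest import logrank_oracle


class TestBhAdjust:
    def test_three_primary_tests_worked_example(self):
        q = bh_adjust([0.030, 0.020, 0.030])
        assert np.allclose(q, [0.030, 0.030, 0.030], atol=1e-12)

    def test_single_p_identity(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_chain(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=8)
            q = bh_adjust(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)
            assert np.all(q >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestWilcoxonRankSum:
    def test_separated_triplets_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.10, abs=1e-12)

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=9)
        assert wilcoxon_rank_sum(x, y).p == pytest.approx(wilcoxon_rank_sum(y, x).p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_full_enumeration(self, seed):
        """Exact p equals enumeration over all C(11,5) group labelings of
        the pooled values (two-sided via |U - n1 n2 / 2|)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        n1 = 5
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        center = n1 * (len(pooled) - n1) / 2
        hits = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                hits += 1
        assert wilcoxon_rank_sum(x, y).p == pytest.approx(hits / total, abs=1e-12)


class TestSpearmanTrend:
    def test_perfect_monotone(self):
        assert spearman_trend([9, 7, 5, 3], [1, 1, 2, 3]).statistic < 0
        assert spearman_trend([3, 2, 1], [3, 2, 1]).statistic == pytest.approx(1.0)
        assert spearman_trend([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            spearman_trend([1.0, 1.0, 1.0], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_rank_pearson_and_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=8)
        t = rng.choice([1, 2, 3], size=8)
        if np.ptp(t) == 0:
            t[0] = t[0] % 3 + 1
        res = spearman_trend(v, t)
        rv, rt = rankdata(v), rankdata(t)
        rho_oracle = np.corrcoef(rv, rt)[0, 1]
        assert res.statistic == pytest.approx(rho_oracle, abs=1e-12)
        hits = 0
        total = 0
        for perm in itertools.permutations(rt):
            total += 1
            r = np.corrcoef(rv, perm)[0, 1]
            if abs(r) >= abs(rho_oracle) - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / total, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        t = np.tile([1, 2], 20)
        res = spearman_trend(v, t)
        assert 0.0 <= res.p <= 1.0


class TestShapiroGate:
    def test_skewed_data_goes_nonparametric(self):
        x = np.random.default_rng(0).exponential(size=50)
        assert shapiro_gate(x) == "nonparametric"

    def test_normal_data_goes_parametric(self):
        x = np.random.default_rng(0).normal(size=50)
        assert shapiro_gate(x) == "parametric"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_gate([3.0, 3.0, 3.0, 3.0])


class TestResponseSummary:
    def test_printed_response_table(self):
        table = response_summary(["PR"] * 4 + ["SD"] * 7 + ["PD"] * 4)
        assert table.loc["DCR", "percent_display"] == 73
        assert table.loc["PR", "percent_display"] == 27
        assert table.loc["SD", "percent_display"] == 47
        assert table.loc["PD", "percent_display"] == 27

    def test_extremes(self):
        assert response_summary(["PD"] * 3).loc["DCR", "percent"] == 0.0
        assert response_summary(["PR"] * 3).loc["DCR", "percent"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            response_summary([])


class TestKaplanMeierLogrank:
    def test_product_limit_by_hand(self):
        res = km_logrank([1, 2], [1, 1], ["A", "A"])
        curve = res.curves["A"]
        by_time = dict(zip(curve.times, curve.survival))
        assert by_time[1.0] == pytest.approx(0.5)
        assert by_time[2.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        res = km_logrank([5, 10, 15, 20], [0, 0, 0, 0], ["A", "A", "B", "B"])
        assert not res.test_evaluable and math.isnan(res.p)
        for curve in res.curves.values():
            assert np.all(curve.survival == 1.0)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, size=12)
        res = km_logrank(t, np.ones(12, int), ["A"] * 12)
        curve = res.curves["A"]
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > time), abs=1e-12)

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(200, size=15)
        e = rng.integers(0, 2, size=15)
        e[0] = 1
        res = km_logrank(t, e, ["A"] * 15)
        surv = res.curves["A"].survival
        assert surv[0] <= 1.0 and np.all(np.diff(surv) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([-1, 2], [1, 1], ["A", "B"])

    @pytest.mark.parametrize("seed", range(3))
    def test_logrank_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(150, size=20), 1)
        e = rng.integers(0, 2, size=20)
        e[:2] = 1
        g = np.array(["A"] * 10 + ["B"] * 10)
        res = km_logrank(t, e, g)
        assert res.p == pytest.approx(logrank_oracle(t, e, g), abs=1e-8)
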