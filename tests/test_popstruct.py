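"""Sensitivity indices, the dip statistic and test, neuron classification."""

import numpy as np
import pytest
from scipy.optimize import linprog

import valuebind as vb
from valuebind._dip import hartigan_dip
from valuebind.popstruct import (classify_gain_vs_heterogeneous, dip_test,
                                 retained_neurons, sensitivity_index,
                                 subspace_contribution)


def _dip_lp_oracle(x, n_xi=15):
    """Exact dip by linear programming over piecewise-linear unimodal CDFs.

    Modes at knots plus a grid of in-gap mode positions with the slope-link
    constraints that couple the convex and concave branches through the gap.
    """
    x = np.sort(np.asarray(x, float))
    n = len(x)
    l = np.arange(n) / n
    u = l + 1.0 / n
    best = np.inf

    def base_rows(nv):
        A, b = [], []
        for i in range(n):
            for val in (u[i], l[i]):
                row = np.zeros(nv); row[i] = 1; row[-1] = -1
                A.append(row); b.append(val)
                row = np.zeros(nv); row[i] = -1; row[-1] = -1
                A.append(row); b.append(-val)
        for i in range(n - 1):
            row = np.zeros(nv); row[i] = 1; row[i + 1] = -1
            A.append(row); b.append(0.0)
        return A, b

    def convex(A, b, nv, i):
        x0, x1, x2 = x[i], x[i + 1], x[i + 2]
        row = np.zeros(nv)
        row[i] -= x2 - x1; row[i + 1] += x2 - x0; row[i + 2] -= x1 - x0
        A.append(row); b.append(0.0)

    def concave(A, b, nv, i):
        x0, x1, x2 = x[i], x[i + 1], x[i + 2]
        row = np.zeros(nv)
        row[i] += x2 - x1; row[i + 1] -= x2 - x0; row[i + 2] += x1 - x0
        A.append(row); b.append(0.0)

    for m in range(n):
        nv = n + 1
        A, b = base_rows(nv)
        for i in range(0, m - 1):
            convex(A, b, nv, i)
        for i in range(m, n - 2):
            concave(A, b, nv, i)
        c = np.zeros(nv); c[-1] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, None)], method="highs")
        if res.success:
            best = min(best, res.fun)

    for m in range(n - 1):
        if x[m + 1] <= x[m]:
            continue
        for xi in np.linspace(x[m], x[m + 1], n_xi + 2)[1:-1]:
            nv = n + 2  # g_0..g_{n-1}, v (CDF value at the mode), t
            A, b = base_rows(nv)
            for i in range(0, m - 1):
                convex(A, b, nv, i)
            for i in range(m + 1, n - 2):
                concave(A, b, nv, i)
            row = np.zeros(nv); row[m] = 1; row[n] = -1; A.append(row); b.append(0.0)
            row = np.zeros(nv); row[n] = 1; row[m + 1] = -1; A.append(row); b.append(0.0)
            row = np.zeros(nv); row[n] = 1; row[-1] = -1; A.append(row); b.append(u[m])
            row = np.zeros(nv); row[n] = -1; row[-1] = -1; A.append(row); b.append(-u[m])
            if m >= 1:
                row = np.zeros(nv)
                row[n] -= x[m] - x[m - 1]
                row[m] += (x[m] - x[m - 1]) + (xi - x[m])
                row[m - 1] -= xi - x[m]
                A.append(row); b.append(0.0)
            if m + 2 <= n - 1:
                row = np.zeros(nv)
                row[m + 1] -= (x[m + 2] - x[m + 1]) + (x[m + 1] - xi)
                row[n] += x[m + 2] - x[m + 1]
                row[m + 2] += x[m + 1] - xi
                A.append(row); b.append(0.0)
            c = np.zeros(nv); c[-1] = 1.0
            res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                          bounds=[(0, 1)] * n + [(None, None), (0, None)],
                          method="highs")
            if res.success:
                best = min(best, res.fun)
    return best


class TestDipStatistic:
    def test_matches_linear_programming_oracle(self):
        rng = np.random.default_rng(0)
        samples = [rng.random(8), rng.standard_normal(10),
                   np.concatenate([rng.normal(0, .05, 6), rng.normal(3, .05, 6)]),
                   rng.exponential(1, 9), rng.random(12)]
        for x in samples:
            assert hartigan_dip(x) == pytest.approx(_dip_lp_oracle(x), abs=1e-7)

    def test_floor_one_over_two_n(self):
        rng = np.random.default_rng(1)
        for n in (2, 5, 20):
            assert hartigan_dip(rng.random(n)) >= 1 / (2 * n) - 1e-12

    def test_extreme_bimodal_limit_one_quarter(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 1e-8, 100), rng.normal(1, 1e-8, 100)]
        assert hartigan_dip(x) == pytest.approx(0.25, abs=1e-3)

    def test_uniform_exceeds_gaussian_on_average(self):
        rng = np.random.default_rng(3)
        uni = np.mean([hartigan_dip(rng.random(300)) for _ in range(30)])
        gau = np.mean([hartigan_dip(rng.standard_normal(300)) for _ in range(30)])
        assert uni > gau


class TestDipTest:
    def test_unimodal_calibration(self):
        rng = np.random.default_rng(4)
        rejections = sum(dip_test(rng.standard_normal(500), n_boot=500, seed=0).p < 0.05
                         for _ in range(50))
        assert rejections <= 5  # at most ~10% of 50 runs

    def test_bimodal_power(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            dip_test(np.r_[rng.normal(-3, 1, 250), rng.normal(3, 1, 250)],
                     n_boot=500, seed=0).p < 0.05
            for _ in range(50))
        assert rejections >= 45  # >= 90%

    def test_uniform_null_p_values_spread(self):
        rng = np.random.default_rng(6)
        ps = [dip_test(rng.random(300), n_boot=500, seed=0).p for _ in range(60)]
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_sample_degenerate(self):
        res = dip_test(np.ones(50), n_boot=100, seed=0)
        assert res.dip == 0.0 and res.p == 1.0

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            dip_test(np.arange(5), n_boot=100, seed=0)


class TestSensitivityIndex:
    def test_identical_sides_give_zero(self):
        prof = np.random.default_rng(7).random((20, 7))
        idx, excl = sensitivity_index(prof, prof.copy())
        assert np.allclose(idx, 0) and not excl

    def test_gain_and_offset_invariance(self):
        prof = np.random.default_rng(8).random((20, 7))
        idx, _ = sensitivity_index(prof, 2.0 * prof + 5.0)
        assert np.abs(idx).max() < 1e-10

    def test_flat_side_excluded(self):
        left = np.random.default_rng(9).random((3, 7))
        right = left.copy()
        right[1] = 4.2  # flat tuning on the right: index undefined
        idx, excl = sensitivity_index(left, right)
        assert excl == [1] and np.isnan(idx[1])


class TestSubspaceContribution:
    def test_one_hot_vector(self):
        v = np.zeros(10)
        v[3] = 2.5
        c = subspace_contribution(v)
        assert c[3] == 1.0 and c.sum() == pytest.approx(1.0)

    def test_equal_weights_uniform(self):
        c = subspace_contribution(np.full(8, -0.7))
        assert np.allclose(c, 1 / 8)

    def test_sums_to_one(self):
        v = np.random.default_rng(10).standard_normal(50)
        assert subspace_contribution(v).sum() == pytest.approx(1.0)

    def test_retention_modes(self):
        v = np.array([10.0, 1.0, 1.0, 1.0, 0.1])
        kept_cum = retained_neurons(v, 0.95, mode="cumulative")
        assert list(kept_cum) == [0]  # the dominant neuron carries > 95%
        kept_cnt = retained_neurons(v, 0.95, mode="count")
        assert len(kept_cnt) == 4

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            subspace_contribution(np.zeros(5))


class TestGainVsHeterogeneous:
    def _levels(self, n_per=40):
        return np.repeat(np.arange(7), n_per)

    def test_planted_gain_recovered(self):
        rng = np.random.default_rng(11)
        levels = self._levels()
        tuning = np.exp(-0.5 * ((np.arange(7) - 3) / 1.5) ** 2)
        hits = 0
        for rep in range(20):
            left = tuning[levels] + 0.3 * rng.standard_normal(len(levels))
            right = 2 * tuning[levels] + 0.3 * rng.standard_normal(len(levels))
            c = classify_gain_vs_heterogeneous(left, levels, right, levels,
                                               n_boot=500, seed=rep)
            hits += c.label == "gain"
        assert hits >= 16  # >= 80%

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(12)
        levels = self._levels()
        hits = 0
        for rep in range(20):
            left = np.exp(-0.5 * (np.arange(7) - 2) ** 2)[levels] \
                + 0.3 * rng.standard_normal(len(levels))
            right = np.exp(-0.5 * (np.arange(7) - 6) ** 2)[levels] \
                + 0.3 * rng.standard_normal(len(levels))
            c = classify_gain_vs_heterogeneous(left, levels, right, levels,
                                               n_boot=500, seed=100 + rep)
            hits += c.label == "heterogeneous"
        assert hits >= 18  # >= 90%

    def test_single_subspace_neurons_not_tested(self):
        c = classify_gain_vs_heterogeneous(None, None, None, None,
                                           in_both_subspaces=False, neuron=7)
        assert c.label == "single_subspace" and c.neuron == 7

    def test_flat_tuning_excluded(self):
        levels = self._levels(5)
        flat = np.ones(len(levels))
        c = classify_gain_vs_heterogeneous(flat, levels, flat, levels,
                                           n_boot=100, seed=0)
        assert c.label == "excluded"
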