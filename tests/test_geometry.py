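"""Crossnobis distances, geometry decomposition, error-rate theory vs oracles."""

import numpy as np
import pytest
from scipy import stats

import valuebind as vb
from valuebind.geometry import (CONDITIONS, binding_error_oracle, ccgp_oracle,
                                crossnobis_matrix, decompose_distances,
                                enumerate_confusable_sets, estimate_geometry,
                                estimate_noise_sigma, estimate_sem_distance,
                                implied_subspace_correlation,
                                predicted_binding_error, predicted_ccgp_error,
                                split_by_condition)


def _cond_data(centroids, n, sigma, rng):
    return {c: centroids[k] + sigma * rng.standard_normal((n, len(centroids[k])))
            for k, c in enumerate(CONDITIONS)}


class TestCrossnobis:
    def test_unbiased_under_null(self):
        rng = np.random.default_rng(0)
        N = 10
        ests = []
        for rep in range(500):
            data = {c: rng.standard_normal((40, N)) for c in CONDITIONS}
            D = crossnobis_matrix(data, n_folds=4, seed=rep)
            ests.append(D[0, 1])
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * se

    def test_known_squared_distance_recovered(self):
        rng = np.random.default_rng(1)
        N = 30
        base = np.zeros(N)
        shift = np.zeros(N)
        shift[0] = 2.0
        cents = [base, base + shift, base, base + shift]
        ests = []
        for rep in range(50):
            data = _cond_data(cents, 200, 1.0, rng)
            ests.append(crossnobis_matrix(data, seed=rep)[0, 1])
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 4.0) < 3 * se

    def test_naive_estimator_positively_biased(self):
        rng = np.random.default_rng(2)
        N = 40
        naive, crossval = [], []
        for rep in range(100):
            data = {c: rng.standard_normal((50, N)) for c in CONDITIONS}
            a, b = data[CONDITIONS[0]], data[CONDITIONS[1]]
            naive.append(np.sum((a.mean(0) - b.mean(0)) ** 2))
            crossval.append(crossnobis_matrix(data, seed=rep)[0, 1])
        assert np.mean(naive) > np.mean(crossval) + 0.5

    def test_too_few_trials_reported_per_condition(self):
        data = {c: np.zeros((3, 5)) for c in CONDITIONS}
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            crossnobis_matrix({**data, (1, 1): np.zeros((2, 5))}, n_folds=5)


class TestDecomposition:
    def _model_matrix(self, d_lv, d_la, d_n):
        D = np.zeros((4, 4))
        vals = {"value": d_lv ** 2 + d_n ** 2, "context": d_la ** 2 + d_n ** 2,
                "diagonal": d_lv ** 2 + d_la ** 2 + d_n ** 2}
        from valuebind.geometry import _PAIR_KIND
        for (i, j), kind in _PAIR_KIND.items():
            D[i, j] = D[j, i] = vals[kind]
        return D

    def test_exact_inverse_problem(self):
        D = self._model_matrix(1.0, 2.0, 0.5)
        (d_lv, d_la, d_n), info = decompose_distances(D)
        assert abs(d_lv - 1.0) < 1e-6
        assert abs(d_la - 2.0) < 1e-6
        assert abs(d_n - 0.5) < 1e-6

    def test_rectangle_recovers_zero_nonlinear(self):
        D = self._model_matrix(1.3, 0.9, 0.0)
        (_, _, d_n), _ = decompose_distances(D)
        assert d_n < 1e-6

    def test_multistart_stability_on_noisy_matrix(self):
        rng = np.random.default_rng(3)
        D = self._model_matrix(1.0, 1.5, 0.8) + 0.05 * rng.standard_normal((4, 4))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        _, info = decompose_distances(D, n_starts=10, seed=4)
        assert info["stability"] < 1e-4

    def test_non_finite_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            decompose_distances(D)


class TestNoiseAndSem:
    def test_zero_noise_gives_zero_sigma(self):
        cents = [np.ones(6) * k for k in range(4)]
        data = {c: np.tile(cents[k], (10, 1)) for k, c in enumerate(CONDITIONS)}
        assert estimate_noise_sigma(data, np.ones(6)) == 0.0

    def test_isotropic_sigma_recovered_within_five_percent(self):
        rng = np.random.default_rng(4)
        data = {c: 0.5 * rng.standard_normal((1000, 20)) for c in CONDITIONS}
        sig = estimate_noise_sigma(data, rng.standard_normal(20))
        assert abs(sig - 0.5) < 0.025

    def test_orthogonal_noise_ignored(self):
        rng = np.random.default_rng(5)
        axis = np.zeros(10)
        axis[0] = 1.0
        noise = rng.standard_normal((500, 10))
        noise[:, 0] = 0.3 * rng.standard_normal(500)
        data = {c: noise.copy() for c in CONDITIONS}
        sig = estimate_noise_sigma(data, axis)
        assert abs(sig - 0.3) < 0.03

    def test_sem_distance_scaling(self):
        rng = np.random.default_rng(6)
        N, sigma = 25, 0.8
        for n in (100, 200):
            data = {c: sigma * rng.standard_normal((n, N)) for c in CONDITIONS}
            eps = estimate_sem_distance(data)
            assert abs(eps - sigma * np.sqrt(N / n)) < 0.1 * sigma * np.sqrt(N / n)
        # doubling trials shrinks eps by ~sqrt(2)
        e1 = estimate_sem_distance({c: sigma * rng.standard_normal((100, N))
                                    for c in CONDITIONS})
        e2 = estimate_sem_distance({c: sigma * rng.standard_normal((200, N))
                                    for c in CONDITIONS})
        assert abs(e1 / e2 - np.sqrt(2)) < 0.2


class TestEnumeration:
    def test_average_confusable_count_is_quarter(self):
        n_s, table = enumerate_confusable_sets(2, 2, 2)
        assert n_s == pytest.approx(0.25)
        # only the diagonal sets are confusable, each with one chimeric twin
        conf = {X: C for X, C in table.items() if C}
        assert len(conf) == 4
        for X, C in conf.items():
            assert len(C) == 1

    def test_single_stimulus_has_no_confusable_sets(self):
        n_s, _ = enumerate_confusable_sets(2, 2, 1)
        assert n_s == 0.0


class TestBindingError:
    def test_zero_noise_limit(self):
        assert predicted_binding_error(1.0, 0.0) == 0.0

    def test_factorized_code_chance_rate(self):
        assert predicted_binding_error(0.0, 1.0) == pytest.approx(0.125)
        assert predicted_binding_error(0.0, 0.0) == pytest.approx(0.125)

    def test_formula_matches_oracle_at_unit_parameters(self):
        spec = vb.syndata.PopulationCodeSpec.create(30, 6.0, 6.0, 1.0, 1.0, seed=1)
        rate, se = binding_error_oracle(spec, n_mc=100_000, seed=2)
        pred = predicted_binding_error(1.0, 1.0)
        assert abs(rate - pred) < 2 * se + 1e-4

    def test_oracle_tie_breaking_at_zero_nonlinear_distance(self):
        spec = vb.syndata.PopulationCodeSpec.create(30, 6.0, 6.0, 0.0, 0.0, seed=3)
        rate, _ = binding_error_oracle(spec, n_mc=40_000, seed=4)
        # 1/4 of presentations are confusable; ties break uniformly
        assert abs(rate - 0.125) < 0.01

    def test_high_snr_oracle_rate_negligible(self):
        spec = vb.syndata.PopulationCodeSpec.create(30, 8.0, 8.0, 10.0, 1.0, seed=5)
        rate, _ = binding_error_oracle(spec, n_mc=20_000, seed=6)
        assert rate < 1e-4


class TestCcgpError:
    def test_chance_when_no_value_signal(self):
        assert predicted_ccgp_error(0.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_analytic_gaussian_value(self):
        # d_N = eps = 0, d_LV = 2 sigma: error = Phi(-1)
        assert predicted_ccgp_error(2.0, 0.0, 1.0, 0.0) == \
            pytest.approx(stats.norm.cdf(-1.0), abs=1e-12)

    def test_zero_noise_limits(self):
        assert predicted_ccgp_error(1.0, 1.0, 0.0) == 0.0
        assert predicted_ccgp_error(0.0, 1.0, 0.0) == 0.5

    def test_formula_matches_prototype_oracle(self):
        for d_lv, d_n in [(1.0, 0.5), (1.5, 1.0), (0.8, 1.5)]:
            spec = vb.syndata.PopulationCodeSpec.create(
                40, d_lv, 1.0, d_n, 1.0, seed=7)
            rate, se = ccgp_oracle(spec, n_mc=50_000, seed=8)
            pred = predicted_ccgp_error(d_lv, d_n, 1.0, 0.0)
            assert abs(rate - pred) < 2 * se + 1e-3, (d_lv, d_n)


class TestImpliedCorrelation:
    @pytest.mark.parametrize("d_lv,d_n,expected",
                             [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 1.0, 0.5)])
    def test_formula_values(self, d_lv, d_n, expected):
        assert implied_subspace_correlation(d_lv, d_n) == pytest.approx(expected)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            implied_subspace_correlation(0.0, 0.0)


class TestEndToEnd:
    def test_geometry_recovery_within_ten_percent(self):
        # stochastic 10% property: assert on the median of three replicates
        true = dict(d_lv=1.0, d_la=2.0, d_n=1.0, sigma=0.5)
        labels = vb.syndata.grid_labels(500)
        errs = {k: [] for k in true}
        for s in (5, 15, 25):
            spec = vb.syndata.PopulationCodeSpec.create(100, seed=s, **true)
            data = vb.syndata.simulate_population(spec, labels, seed=s + 1)
            est = estimate_geometry(data, labels, seed=s + 2)
            for k in true:
                errs[k].append(abs(getattr(est, k) - true[k]) / true[k])
        for k, e in errs.items():
            assert np.median(e) < 0.10, (k, e)

    def test_binding_blind_to_linear_value_distance(self):
        # the misbinding rate depends on (d_N, sigma) only: the oracle should
        # not move when d_LV changes (as long as non-chimeric sets stay far)
        rates = []
        for d_lv in (4.0, 8.0):
            spec = vb.syndata.PopulationCodeSpec.create(30, d_lv, 6.0, 1.0, 1.0,
                                                        seed=9)
            rate, se = binding_error_oracle(spec, n_mc=60_000, seed=10)
            rates.append((rate, se))
        (r1, s1), (r2, s2) = rates
        assert abs(r1 - r2) < 2 * np.hypot(s1, s2) + 1e-3

    def test_ccgp_blind_to_context_distance(self):
        rates = []
        for d_la in (0.5, 3.0):
            spec = vb.syndata.PopulationCodeSpec.create(30, 1.2, d_la, 1.0, 1.0,
                                                        seed=11)
            rate, se = ccgp_oracle(spec, n_mc=60_000, seed=12)
            rates.append((rate, se))
        (r1, s1), (r2, s2) = rates
        assert abs(r1 - r2) < 2 * np.hypot(s1, s2) + 1e-3
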