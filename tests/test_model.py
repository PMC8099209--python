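"""Ordinal mixed autoregressive model: pmf, likelihood, fitting, prediction."""

import numpy as np
import pytest

import adforecast as af
from adforecast.model import (
    FitOptions,
    _adaptive_loglik,
    _cut_ext,
    _pairs_to_arrays,
)
from adforecast.panel import TransitionPair


def make_pairs(rng, n_patients, n_days, beta, cuts, sigma, gamma=(), x_sd=1.0):
    """Simulate pairs directly from the transition model."""
    params = af.OrderedLogisticParams(tuple(cuts))
    beta_ext = np.concatenate([np.asarray(beta, dtype=float), [0.0]])
    pairs = []
    for k in range(n_patients):
        a = rng.normal(0, sigma)
        s = int(rng.integers(0, 5))
        for t in range(1, n_days):
            x = tuple(rng.normal(0, x_sd) for _ in gamma)
            eta = a + beta_ext[s] + float(np.dot(gamma, x))
            pmf = af.ordered_logistic_pmf(eta, params)
            s2 = int(rng.choice(5, p=pmf / pmf.sum()))
            pairs.append(TransitionPair(f"p{k}", t, s, s2, covariates=x))
            s = s2
    return pairs


def brute_force_marginal_ll(beta, gamma, cuts, sigma, pairs_by_patient, n_grid=20001):
    """Trapezoid integration over alpha in [-10 sigma, 10 sigma], per patient."""
    params = af.OrderedLogisticParams(tuple(cuts))
    beta_ext = np.concatenate([np.asarray(beta, dtype=float), [0.0]])
    total = 0.0
    grid = np.linspace(-10 * sigma, 10 * sigma, n_grid)
    log_prior = -0.5 * (grid / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    for plist in pairs_by_patient.values():
        log_int = log_prior.copy()
        for p in plist:
            eta = grid + beta_ext[p.s_t] + float(np.dot(gamma, p.covariates))
            cdf_hi = 1 / (1 + np.exp(-(np.append(cuts, np.inf)[p.s_next] - eta)))
            cdf_lo = 1 / (1 + np.exp(-(np.append(-np.inf, cuts)[p.s_next] - eta)))
            log_int += np.log(np.clip(cdf_hi - cdf_lo, 1e-300, 1.0))
        m = log_int.max()
        total += m + np.log(np.trapezoid(np.exp(log_int - m), grid))
    return total


CUTS = (-2.0, -1.0, 1.0, 2.0)


class TestEncoding:
    @pytest.mark.parametrize(
        "s,expected",
        [(0, [1, 0, 0, 0]), (2, [0, 0, 1, 0]), (3, [0, 0, 0, 1]), (4, [0, 0, 0, 0])],
    )
    def test_indicator_with_reference_category_four(self, s, expected):
        np.testing.assert_array_equal(af.encode_previous_score(s), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            af.encode_previous_score(5)


class TestOrderedLogisticPmf:
    def test_extreme_location_concentrates_on_top_category(self):
        pmf = af.ordered_logistic_pmf(50.0, af.OrderedLogisticParams(CUTS))
        assert pmf[4] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_cutpoints_give_symmetric_pmf(self):
        pmf = af.ordered_logistic_pmf(0.0, af.OrderedLogisticParams(CUTS))
        assert pmf[0] == pytest.approx(pmf[4])
        assert pmf[1] == pytest.approx(pmf[3])

    def test_known_values_from_logistic_cdf_differences(self):
        pmf = af.ordered_logistic_pmf(0.0, af.OrderedLogisticParams(CUTS))
        np.testing.assert_allclose(
            pmf, [0.11920, 0.14973, 0.46212, 0.14973, 0.11920], atol=1e-5
        )

    def test_non_monotone_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            af.OrderedLogisticParams((0.0, -1.0, 1.0, 2.0))


class TestMarginalLikelihood:
    def _fixture(self, n_patients=3, n_days=8, seed=0):
        rng = np.random.default_rng(seed)
        pairs = make_pairs(rng, n_patients, n_days, (-1.0, -0.5, 0.0, 0.5), CUTS, 1.0)
        by_patient = {}
        for p in pairs:
            by_patient.setdefault(p.patient, []).append(p)
        return by_patient

    def test_sigma_zero_degenerates_to_plain_likelihood(self):
        by_patient = self._fixture()
        beta = (-1.0, -0.5, 0.0, 0.5)
        ll0 = af.log_marginal_likelihood(beta, (), af.OrderedLogisticParams(CUTS), 0.0, by_patient)
        plain = 0.0
        for plist in by_patient.values():
            for p in plist:
                eta = beta[p.s_t] if p.s_t <= 3 else 0.0
                plain += np.log(af.ordered_logistic_pmf(eta, af.OrderedLogisticParams(CUTS))[p.s_next])
        assert ll0 == pytest.approx(plain, abs=1e-10)

    def test_single_pair_matches_bruteforce_integral(self):
        by_patient = {"p0": [TransitionPair("p0", 1, 2, 3)]}
        beta = (-1.0, -0.5, 0.0, 0.5)
        ll = af.log_marginal_likelihood(beta, (), af.OrderedLogisticParams(CUTS), 1.0,
                                        by_patient, quad_order=15)
        oracle = brute_force_marginal_ll(beta, (), CUTS, 1.0, by_patient)
        assert ll == pytest.approx(oracle, rel=1e-6)

    def test_duplicated_data_is_not_twice_the_loglik(self):
        by_patient = self._fixture()
        beta = (-1.0, -0.5, 0.0, 0.5)
        params = af.OrderedLogisticParams(CUTS)
        ll1 = af.log_marginal_likelihood(beta, (), params, 1.0, by_patient)
        doubled = {k: v + v for k, v in by_patient.items()}
        ll2 = af.log_marginal_likelihood(beta, (), params, 1.0, doubled)
        assert ll2 != pytest.approx(2 * ll1, abs=1e-6)

    def test_quadrature_order_converged_by_nine_nodes(self):
        by_patient = self._fixture(n_patients=15, n_days=12, seed=2)
        beta = (-1.0, -0.5, 0.0, 0.5)
        params = af.OrderedLogisticParams(CUTS)
        ll9 = af.log_marginal_likelihood(beta, (), params, 1.0, by_patient, quad_order=9)
        ll25 = af.log_marginal_likelihood(beta, (), params, 1.0, by_patient, quad_order=25)
        assert abs(ll9 - ll25) <= 1e-4

    def test_invalid_inputs_rejected(self):
        by_patient = self._fixture()
        with pytest.raises(ValueError):
            af.log_marginal_likelihood((0, 0, 0, 0), (), af.OrderedLogisticParams(CUTS),
                                       -0.5, by_patient)


class TestFit:
    def test_recovers_generator_parameters_at_moderate_scale(self):
        rng = np.random.default_rng(3)
        beta_true = (-2.5, -1.5, -0.5, 0.25)
        pairs = make_pairs(rng, 40, 120, beta_true, CUTS, 0.8)
        m = af.fit_sign_model(pairs, af.ModelSpec("dryness"))
        assert m.fit_meta["converged"]
        np.testing.assert_allclose(m.beta, beta_true, atol=0.4)
        np.testing.assert_allclose(m.cutpoints.cutpoints, CUTS, atol=0.4)
        assert m.sigma_alpha == pytest.approx(0.8, abs=0.25)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(4)
        pairs = make_pairs(rng, 8, 30, (-1, -1, 0, 0), CUTS, 1.0)
        m1 = af.fit_sign_model(pairs, af.ModelSpec("itching"))
        m2 = af.fit_sign_model(pairs, af.ModelSpec("itching"))
        np.testing.assert_array_equal(m1.beta, m2.beta)
        assert m1.sigma_alpha == m2.sigma_alpha

    def test_single_patient_flags_weak_identifiability(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng, 1, 60, (-1, -1, 0, 0), CUTS, 1.0)
        m = af.fit_sign_model(pairs, af.ModelSpec("dryness"))
        assert any("identified" in w for w in m.fit_meta["warnings"])

    def test_single_outcome_category_rejected(self):
        pairs = [TransitionPair("A", d, 0, 0) for d in range(1, 10)]
        with pytest.raises(ValueError, match="categories"):
            af.fit_sign_model(pairs, af.ModelSpec("dryness"))

    def test_loglik_trace_is_monotone(self, fitted_small_model):
        model, _, _ = fitted_small_model
        trace = model.fit_meta["ll_trace"]
        assert np.all(np.diff(trace) > -1e-6)

    def test_fitted_persistence_is_monotone_in_previous_score(self, fitted_small_model):
        model, _, _ = fitted_small_model
        p_ge2 = [
            af.predict_forecast(model, "nobody", s)[2:].sum() for s in range(5)
        ]
        assert np.all(np.diff(p_ge2) >= -1e-12)

    def test_single_covariate_null_estimate_is_small(self):
        rng = np.random.default_rng(6)
        pairs = make_pairs(rng, 30, 80, (-2, -1, 0, 0.5), CUTS, 1.0, gamma=(0.0,))
        m = af.fit_sign_model(
            pairs, af.ModelSpec("dryness", ("temp",)), FitOptions(compute_se=True)
        )
        assert abs(m.gamma[0]) < 0.15
        assert m.gamma_se is not None and m.gamma_se[0] > 0


class TestEmpiricalBayes:
    def test_no_pairs_returns_prior_mean(self, fitted_small_model):
        model, _, _ = fitted_small_model
        assert af.eb_alpha(model, []) == 0.0

    def test_degenerate_prior_returns_zero(self, fitted_small_model):
        model, pairs, _ = fitted_small_model
        import copy
        m0 = copy.copy(model)
        m0.sigma_alpha = 0.0
        some = [p for p in pairs if p.patient == pairs[0].patient]
        assert af.eb_alpha(m0, some) == 0.0

    def test_persistently_high_patient_gets_positive_alpha(self, fitted_small_model):
        model, _, _ = fitted_small_model
        high = [TransitionPair("new", d, 4, 4) for d in range(1, 15)]
        assert af.eb_alpha(model, high) > 0.5

    def test_mode_matches_bruteforce_grid_search(self, fitted_small_model):
        model, pairs, _ = fitted_small_model
        patient = pairs[0].patient
        mine = [p for p in pairs if p.patient == patient]
        a_hat = af.eb_alpha(model, mine)
        grid = np.linspace(-5, 5, 20001)
        beta_ext = np.concatenate([model.beta, [0.0]])
        logp = -0.5 * (grid / model.sigma_alpha) ** 2
        c = np.asarray(model.cutpoints.cutpoints)
        for p in mine:
            eta = grid + beta_ext[p.s_t]
            hi = 1 / (1 + np.exp(-(np.append(c, np.inf)[p.s_next] - eta)))
            lo = 1 / (1 + np.exp(-(np.append(-np.inf, c)[p.s_next] - eta)))
            logp += np.log(np.clip(hi - lo, 1e-300, 1))
        assert a_hat == pytest.approx(grid[np.argmax(logp)], abs=1e-3)


class TestPrediction:
    def test_no_covariate_forecast_depends_only_on_patient_and_score(self, fitted_small_model):
        model, _, _ = fitted_small_model
        patient = list(model.alpha_hat)[0]
        f1 = af.predict_forecast(model, patient, 2)
        f2 = af.predict_forecast(model, patient, 2)
        np.testing.assert_array_equal(f1, f2)
        with pytest.raises(ValueError):
            af.predict_forecast(model, "x", 2, covariates=(1.0,))

    def test_unknown_patient_gets_population_forecast(self, fitted_small_model):
        model, _, _ = fitted_small_model
        pop = af.ordered_logistic_pmf(float(model.beta[2]), model.cutpoints)
        np.testing.assert_allclose(af.predict_forecast(model, "stranger", 2), pop)

    def test_forecasts_are_valid_pmfs(self, fitted_small_model):
        model, _, _ = fitted_small_model
        rng = np.random.default_rng(8)
        for _ in range(200):
            pmf = af.predict_forecast(model, rng.choice(list(model.alpha_hat)),
                                      int(rng.integers(0, 5)))
            assert pmf.min() >= 0
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_serialization_round_trip_is_exact(self, tmp_path, fitted_small_model):
        model, _, _ = fitted_small_model
        path = tmp_path / "model.json"
        af.save_model(model, path)
        loaded = af.load_model(path)
        np.testing.assert_array_equal(loaded.beta, model.beta)
        assert loaded.cutpoints.cutpoints == model.cutpoints.cutpoints
        assert loaded.sigma_alpha == model.sigma_alpha
        assert loaded.alpha_hat == model.alpha_hat
        assert loaded.fit_meta["loglik"] == model.fit_meta["loglik"]
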