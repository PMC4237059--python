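"""MAP inversion, Laplace evidence, Bayes factors, MCMC: oracles and contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgfilter.exceptions import ModelViolationError
from hgfilter.inversion import (
    Prior,
    bayes_factor,
    check_identifiability,
    fit_map,
    inversion_example_priors,
    laplace_from_callable,
    laplace_log_evidence,
    log_prior,
    metropolis_gibbs,
    objective_Z,
    sample_posterior_mcmc,
    simulation_study_priors,
    transform_parameters,
)
from hgfilter.responses import ResponseModelSpec, ResponseParams


class TestTransforms:
    def test_logit_midpoint_maps_to_zero(self):
        p = Prior("logit", 0.0, 1.0, bound=2.0)
        assert p.to_estimation(1.0) == 0.0
        assert p.to_native(0.0) == 1.0

    def test_logit_known_point(self):
        # x = a/(1+e) has logit exactly -1 for any bound a
        for a in (0.005, 2.0, 6.0):
            p = Prior("logit", 0.0, 1.0, bound=a)
            assert p.to_estimation(a / (1.0 + math.e)) == pytest.approx(-1.0, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e6))
    def test_log_round_trip(self, x):
        p = Prior("log", 0.0, 1.0)
        assert p.to_native(p.to_estimation(x)) == pytest.approx(x, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1e-4, 5.9999))
    def test_logit_round_trip(self, x):
        p = Prior("logit", 0.0, 1.0, bound=6.0)
        assert p.to_native(p.to_estimation(x)) == pytest.approx(x, rel=1e-10)

    def test_out_of_domain_rejected(self):
        p = Prior("logit", 0.0, 1.0, bound=6.0)
        with pytest.raises(ValueError):
            p.to_estimation(6.5)
        with pytest.raises(ValueError):
            Prior("log", 0.0, 1.0).to_estimation(-1.0)

    def test_dict_interface(self):
        specs = {"a": Prior("log", 0.0, 1.0), "b": Prior("native", 0.0, 1.0)}
        est = transform_parameters({"a": 2.0, "b": -3.0}, specs, "to_estimation")
        back = transform_parameters(est, specs, "to_native")
        assert back["a"] == pytest.approx(2.0, rel=1e-12) and back["b"] == -3.0


class TestLogPrior:
    def test_standard_normal_at_mean(self):
        priors = {"w": Prior("native", 0.7, 1.0)}
        assert log_prior({"w": 0.7}, priors) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_factorizes_over_parameters(self):
        priors = {"a": Prior("native", 0.0, 2.0), "b": Prior("log", 1.0, 3.0)}
        total = log_prior({"a": 0.5, "b": -0.2}, priors)
        pa = log_prior({"a": 0.5}, {"a": priors["a"]})
        pb = log_prior({"b": -0.2}, {"b": priors["b"]})
        assert total == pytest.approx(pa + pb, rel=1e-12)

    def test_fixed_parameters_contribute_zero(self):
        priors = {"a": Prior("native", 0.0, 1.0), "c": Prior("native", -4.0, 0.0)}
        assert log_prior({"a": 0.3}, priors) == log_prior(
            {"a": 0.3}, {"a": priors["a"]})

    def test_worked_example_prior_set_accepted(self):
        priors = inversion_example_priors()
        fixed = {n for n, p in priors.items() if p.fixed}
        assert fixed == {"mu3_0", "omega"}
        assert priors["kappa"].bound == 6.0
        assert priors["theta"].bound == 0.005
        assert priors["zeta"].mean == pytest.approx(math.log(48.0))
        free_priors = inversion_example_priors("volatility_temperature")
        assert "zeta" not in free_priors
        assert not free_priors["mu3_0"].fixed and not free_priors["omega"].fixed


class TestObjective:
    def test_decomposes_into_likelihood_and_prior(self, simulated_subject):
        from hgfilter.responses import log_likelihood_series

        series, true, traj = simulated_subject
        priors = simulation_study_priors()
        xi = {n: priors[n].to_estimation(true[n])
              for n in priors if not priors[n].fixed}
        Z = objective_Z(xi, series, ResponseModelSpec("unit_square_sigmoid"), priors)
        spec = ResponseModelSpec("unit_square_sigmoid", ResponseParams(true["zeta"]))
        ll = log_likelihood_series(traj, series.y, spec)
        lp = log_prior(xi, priors)
        assert Z == pytest.approx(ll + lp, rel=1e-12)
        assert math.isfinite(Z)

    def test_fixed_parameters_are_immutable(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        xi = {n: priors[n].mean for n in priors if not priors[n].fixed}
        xi["omega"] = -3.0  # fixed parameter: must be rejected, not absorbed
        with pytest.raises(ValueError, match="fixed"):
            objective_Z(xi, series, ResponseModelSpec("unit_square_sigmoid"), priors)

    def test_noisy_input_channel_uses_reference_filter(self, simulated_subject):
        """Fitting with a noisy sensory channel routes through the
        reference filter and still yields a finite objective."""
        from hgfilter.binary import BinaryInputModel

        series, _, _ = simulated_subject
        rng = np.random.default_rng(55)
        noisy_u = series.u + rng.standard_normal(series.K) * 0.1
        noisy_series = type(series)(u=noisy_u, y=series.y)
        priors = simulation_study_priors()
        xi = {n: priors[n].mean for n in priors if not priors[n].fixed}
        Z = objective_Z(xi, noisy_series, ResponseModelSpec("unit_square_sigmoid"),
                        priors, input_model=BinaryInputModel("noisy", pi_hat_u=10.0))
        assert math.isfinite(Z)

    def test_sentinel_vs_exception(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        xi = {n: priors[n].mean for n in priors if not priors[n].fixed}
        xi["sigma3_0"] = -800.0  # exp(-800) underflows to a zero variance
        bad = objective_Z(xi, series, ResponseModelSpec("unit_square_sigmoid"),
                          priors, sentinel=True)
        assert bad <= -1e11
        with pytest.raises((ModelViolationError, ValueError, ZeroDivisionError,
                            OverflowError)):
            objective_Z(xi, series, ResponseModelSpec("unit_square_sigmoid"),
                        priors, sentinel=False)


class TestFitMap:
    def test_zero_free_parameters_returns_fixed_values(self, simulated_subject):
        series, true, _ = simulated_subject
        priors = {
            name: Prior(p.space, p.to_estimation(true[name]), 0.0, p.bound)
            for name, p in simulation_study_priors().items()
        }
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors)
        assert fit.free_names == []
        assert fit.n_function_evals == 1
        assert fit.xi_map["kappa"] == pytest.approx(true["kappa"], rel=1e-9)

    def test_recovers_kappa_within_sanity_band(self, simulated_subject):
        series, true, _ = simulated_subject
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"),
                      simulation_study_priors(), seed=0, restarts=1)
        assert abs(fit.xi_map["kappa"] - true["kappa"]) < 1.0
        assert fit.converged

    def test_restart_from_map_is_a_fixed_point(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors,
                      seed=0, restarts=0)
        restarted = {name: Prior(priors[name].space, fit.xi_map_est[name],
                                 priors[name].variance, priors[name].bound)
                     if name in fit.xi_map_est else priors[name]
                     for name in priors}
        # starting the simplex at the optimum must not move away
        refit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"),
                        restarted, seed=0, restarts=0)
        # same basin: objective cannot get meaningfully worse
        assert refit.objective >= fit.objective - 1e-3

    def test_objective_field_matches_reevaluation(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors,
                      seed=0, restarts=0)
        assert objective_Z(fit.xi_map_est, series,
                           ResponseModelSpec("unit_square_sigmoid"),
                           priors) == pytest.approx(fit.objective, rel=1e-12)

    def test_deterministic_given_seed(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        a = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors, seed=3)
        b = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors, seed=3)
        assert a.xi_map == b.xi_map and a.objective == b.objective


class TestLaplace:
    def test_no_free_parameters_returns_objective(self, simulated_subject):
        series, true, _ = simulated_subject
        priors = {
            name: Prior(p.space, p.to_estimation(true[name]), 0.0, p.bound)
            for name, p in simulation_study_priors().items()
        }
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors)
        F = laplace_log_evidence(fit, series,
                                 ResponseModelSpec("unit_square_sigmoid"), priors)
        assert F == fit.objective

    def test_exact_on_gaussian_toy(self):
        """On a quadratic log-joint the Laplace value equals the analytic
        Gaussian integral ln(integral exp(Z) dx)."""
        A = np.array([[2.0, 0.3], [0.3, 1.5]])  # precision of the toy posterior
        c = -1.7

        def Z(x):
            return c - 0.5 * x @ A @ x

        # analytic: ln integral = c + (d/2) ln(2 pi) - 1/2 ln det A
        exact = c + math.log(2 * math.pi) - 0.5 * math.log(np.linalg.det(A))
        F = laplace_from_callable(Z, np.zeros(2))
        assert F == pytest.approx(exact, abs=1e-6)

    def test_occam_penalty_for_irrelevant_parameter(self):
        # adding a free parameter that the likelihood ignores costs evidence
        def Z1(x):
            return -0.5 * x[0] ** 2 - 0.5 * math.log(2 * math.pi)

        def Z2(x):
            # same likelihood, plus a sharp prior on an irrelevant x[1]
            return Z1(x[:1]) - 0.5 * (x[1] / 0.1) ** 2 \
                - 0.5 * math.log(2 * math.pi * 0.1 ** 2)

        F1 = laplace_from_callable(Z1, np.zeros(1))
        # the irrelevant parameter integrates out exactly here, so compare a
        # model whose extra dimension the likelihood *does* constrain twice
        def Z2_constrained(x):
            return Z2(x) - 0.5 * (x[1] - 3.0) ** 2  # conflicting constraint
        F2 = laplace_from_callable(Z2_constrained, np.array([0.0, 3.0 * 0.01 / 1.01]))
        assert F2 < F1

    def test_nonpositive_definite_is_repaired_with_warning(self):
        def Z(x):
            return 0.5 * x[0] ** 2  # maximum nowhere: negative Hessian is -1

        with pytest.warns(RuntimeWarning, match="positive definite"):
            F = laplace_from_callable(Z, np.zeros(1))
        assert math.isfinite(F)


class TestBayesFactor:
    def test_equal_evidence_gives_one(self):
        assert bayes_factor(-10.0, -10.0) == 1.0

    def test_worked_example_rounds_to_1556(self):
        assert round(bayes_factor(-196.19, -188.84)) == 1556

    def test_reciprocal_identity(self):
        assert bayes_factor(-3.0, -7.0) * bayes_factor(-7.0, -3.0) == pytest.approx(
            1.0, rel=1e-12)


class TestMCMC:
    def test_conjugate_toy_matches_closed_form(self):
        """Gaussian prior N(0,1) x Gaussian likelihood N(2, 0.5) posterior:
        precision 3, mean 4/3; the sampler must agree within MC error."""

        def logp(x):
            return -0.5 * x[0] ** 2 - 0.5 * (x[0] - 2.0) ** 2 / 0.5

        rng = np.random.default_rng(17)
        samples, _, acc = metropolis_gibbs(logp, np.zeros(1), np.array([1.0]),
                                           chain_length=30_000, burn_in=3_000,
                                           rng=rng)
        post_mean, post_var = 4.0 / 3.0, 1.0 / 3.0
        se = math.sqrt(post_var / 2_000)  # generous: correlated draws
        assert abs(samples.mean() - post_mean) < 4 * se * 5
        assert samples.var() == pytest.approx(post_var, rel=0.1)
        assert 0.1 < acc[0] < 0.95

    def test_same_seed_identical_chain(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        kwargs = dict(chain_length=1200, burn_in=300)
        a = sample_posterior_mcmc(series, ResponseModelSpec("unit_square_sigmoid"),
                                  priors, seed=9, **kwargs)
        b = sample_posterior_mcmc(series, ResponseModelSpec("unit_square_sigmoid"),
                                  priors, seed=9, **kwargs)
        assert np.array_equal(a.samples, b.samples)

    def test_map_inside_posterior_interval(self, simulated_subject):
        series, _, _ = simulated_subject
        priors = simulation_study_priors()
        fit = fit_map(series, ResponseModelSpec("unit_square_sigmoid"), priors,
                      seed=0, restarts=0)
        mcmc = sample_posterior_mcmc(series, ResponseModelSpec("unit_square_sigmoid"),
                                     priors, chain_length=8000, burn_in=1000, seed=1,
                                     start=fit.xi_map_est)
        lo, hi = mcmc.pci95["kappa"]
        assert lo <= fit.xi_map["kappa"] <= hi


class TestIdentifiability:
    def test_warns_when_level3_unconstrained(self):
        priors = simulation_study_priors()
        priors["omega"] = Prior("native", -4.0, 1.0)  # free omega and kappa
        with pytest.warns(UserWarning, match="mu3_0"):
            msgs = check_identifiability(ResponseModelSpec("unit_square_sigmoid"),
                                         priors)
        assert len(msgs) == 1

    def test_dynamic_temperature_frees_all_parameters(self):
        priors = inversion_example_priors("volatility_temperature")
        assert check_identifiability(
            ResponseModelSpec("volatility_temperature"), priors) == []

    def test_fully_fixed_level_passes(self):
        priors = simulation_study_priors()  # mu3_0 and omega fixed
        assert check_identifiability(
            ResponseModelSpec("unit_square_sigmoid"), priors) == []
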