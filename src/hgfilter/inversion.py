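"""Inversion of the HGF/decision-model combination from observed choices.

"Observing the observer": the experimenter infers the parameters

    xi = {chi, lambda(0), zeta}
       = {kappa, omega, theta, mu_i(0), sigma_i(0), zeta}

of an agent who itself filters inputs u with an HGF and maps beliefs to
choices y through a response model.  The objective is the log-joint

    Z(xi) = sum_k ln p(y^(k) | lambda^(k)(chi, lambda(0), u), zeta) + ln p(xi),

maximized to give the MAP estimate xi*.  Priors are Gaussian in
transformed estimation spaces — native for unbounded parameters, log for
positive ones (variances, zeta), and a scaled logit for doubly bounded
ones (kappa, theta), logit_a(x) = ln(x / (a - x)).  A prior variance of
zero fixes a parameter and removes it from the search.

Model evidence is approximated at the MAP by the Laplace assumption
(Gaussian posterior with the negative Hessian of Z as precision), and
full posteriors by Metropolis-within-Gibbs sampling in estimation space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from hgfilter import _fast
from hgfilter.binary import (
    BinaryHGFParams,
    BinaryInputModel,
    filter_sequence_binary,
)
from hgfilter.continuous import InitialBelief, Trajectory, TrialSeries
from hgfilter.exceptions import HGFError, ModelViolationError
from hgfilter.responses import EPS, ResponseModelSpec, _unit_square_log_p1

__all__ = [
    "Prior",
    "FitResult",
    "MCMCResult",
    "transform_parameters",
    "log_prior",
    "objective_Z",
    "fit_map",
    "laplace_log_evidence",
    "laplace_from_callable",
    "bayes_factor",
    "sample_posterior_mcmc",
    "metropolis_gibbs",
    "check_identifiability",
    "inversion_example_priors",
    "simulation_study_priors",
]

# value of -inf replacement handed to optimizers when the filter breaks down
SENTINEL = -1e12

# canonical parameter order for the three-level binary model
PARAM_ORDER = ("mu2_0", "sigma2_0", "mu3_0", "sigma3_0", "kappa", "omega", "theta", "zeta")


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on one parameter in its estimation space.

    space: "native", "log", or "logit" (requires an upper bound > 0).
    mean/variance are given *in estimation space*; variance 0 fixes the
    parameter at the native image of the mean.
    """

    space: str
    mean: float
    variance: float
    bound: float | None = None

    def __post_init__(self):
        if self.space not in ("native", "log", "logit"):
            raise ValueError(f"unknown estimation space {self.space!r}")
        if self.variance < 0:
            raise ValueError("prior variance must be non-negative")
        if self.space == "logit":
            if self.bound is None or not self.bound > 0:
                raise ValueError("logit space requires an upper bound a > 0")
        elif self.bound is not None:
            raise ValueError("bound is only meaningful in logit space")

    @property
    def fixed(self) -> bool:
        return self.variance == 0.0

    def to_native(self, x_est: float) -> float:
        if self.space == "native":
            return float(x_est)
        if self.space == "log":
            return math.exp(x_est)
        return self.bound / (1.0 + math.exp(-x_est))

    def to_estimation(self, x_native: float) -> float:
        if self.space == "native":
            return float(x_native)
        if self.space == "log":
            if not x_native > 0:
                raise ValueError(f"log space requires a positive value, got {x_native}")
            return math.log(x_native)
        if not 0 < x_native < self.bound:
            raise ValueError(
                f"logit space with bound {self.bound} requires a value in "
                f"(0, {self.bound}), got {x_native}")
        return math.log(x_native / (self.bound - x_native))

    @property
    def native_mean(self) -> float:
        return self.to_native(self.mean)


def transform_parameters(values, specs, direction: str):
    """Map parameter values between native and estimation space.

    ``values``/``specs`` are aligned sequences (or dicts with shared
    keys); ``direction`` is "to_native" or "to_estimation".
    """
    if direction not in ("to_native", "to_estimation"):
        raise ValueError("direction must be 'to_native' or 'to_estimation'")
    if isinstance(values, dict):
        return {k: getattr(specs[k], direction)(v) for k, v in values.items()}
    return [getattr(s, direction)(v) for v, s in zip(values, specs, strict=True)]


def log_prior(xi_est: dict[str, float], priors: dict[str, Prior]) -> float:
    """Sum of Gaussian log-densities over the free parameters.

    Fixed (variance-0) parameters contribute zero; the factorized prior
    is a plain sum of marginals.
    """
    total = 0.0
    for name, prior in priors.items():
        if prior.fixed:
            continue
        x = xi_est[name]
        total += -0.5 * math.log(2.0 * math.pi * prior.variance) \
                 - 0.5 * (x - prior.mean) ** 2 / prior.variance
    return total


def inversion_example_priors(family: str = "unit_square_sigmoid") -> dict[str, Prior]:
    """Prior set of the worked single-subject inversion.

    For the constant-zeta unit-square sigmoid: mu2_0 native (0,1),
    sigma2_0 log (0,1), mu3_0 fixed at 1, sigma3_0 log (0,1), kappa
    logit(6) (0,2), omega fixed at -4, theta logit(0.005) (0,2), zeta
    log (ln 48, 1).  The dynamic-temperature models make mu_3 observable
    through behavior, so mu3_0 and omega are freed (variance 4) and zeta
    is dropped.
    """
    priors = {
        "mu2_0": Prior("native", 0.0, 1.0),
        "sigma2_0": Prior("log", 0.0, 1.0),
        "mu3_0": Prior("native", 1.0, 0.0),
        "sigma3_0": Prior("log", 0.0, 1.0),
        "kappa": Prior("logit", 0.0, 2.0, bound=6.0),
        "omega": Prior("native", -4.0, 0.0),
        "theta": Prior("logit", 0.0, 2.0, bound=0.005),
        "zeta": Prior("log", math.log(48.0), 1.0),
    }
    if family in ("volatility_temperature", "precision_temperature"):
        priors["mu3_0"] = Prior("native", 1.0, 4.0)
        priors["omega"] = Prior("native", -4.0, 4.0)
        del priors["zeta"]
    return priors


def simulation_study_priors() -> dict[str, Prior]:
    """Prior set of the parameter-recovery study (six free parameters).

    mu2_0 native (0,1); sigma2_0, sigma3_0 log (0,1); kappa logit(6)
    (0,9); theta logit(0.005) (0,9); zeta log (ln 48, 1) — the high zeta
    prior mean shrinks decision-noise estimates; mu3_0 and omega fixed
    (1 and -4).
    """
    return {
        "mu2_0": Prior("native", 0.0, 1.0),
        "sigma2_0": Prior("log", 0.0, 1.0),
        "mu3_0": Prior("native", 1.0, 0.0),
        "sigma3_0": Prior("log", 0.0, 1.0),
        "kappa": Prior("logit", 0.0, 9.0, bound=6.0),
        "omega": Prior("native", -4.0, 0.0),
        "theta": Prior("logit", 0.0, 9.0, bound=0.005),
        "zeta": Prior("log", math.log(48.0), 1.0),
    }


def _check_prior_names(priors: dict[str, Prior], response: ResponseModelSpec) -> None:
    needed = set(PARAM_ORDER) - ({"zeta"} if not response.has_zeta else set())
    missing = needed - set(priors)
    if missing:
        raise ValueError(f"priors missing for {sorted(missing)}")
    extra = set(priors) - needed
    if extra:
        raise ValueError(f"unexpected prior entries {sorted(extra)}")


class _Objective:
    """Evaluator of Z over the free parameters in estimation space.

    Uses the compiled three-level filter in the noiseless case and the
    reference implementation otherwise.
    """

    def __init__(self, series: TrialSeries, response: ResponseModelSpec,
                 priors: dict[str, Prior], input_model: BinaryInputModel | None = None):
        if series.y is None:
            raise ValueError("fitting requires a response column y")
        _check_prior_names(priors, response)
        self.series = series
        self.response = response
        self.priors = priors
        self.input_model = input_model or BinaryInputModel("noiseless")
        self.free_names = [n for n in PARAM_ORDER if n in priors and not priors[n].fixed]
        self.fixed_native = {n: p.native_mean for n, p in priors.items() if p.fixed}
        self.n_calls = 0
        self._y = np.asarray(series.y, dtype=float)
        self._obs = ~np.isnan(self._y)
        # the compiled path covers the standard case: three levels,
        # noiseless binary input, no missing inputs
        self._fast_ok = (self.input_model.mode == "noiseless"
                         and not np.isnan(series.u).any())

    @property
    def x0(self) -> np.ndarray:
        return np.array([self.priors[n].mean for n in self.free_names])

    @property
    def prior_sd(self) -> np.ndarray:
        return np.array([math.sqrt(self.priors[n].variance) for n in self.free_names])

    def natives(self, x_est: np.ndarray) -> dict[str, float]:
        out = dict(self.fixed_native)
        for name, value in zip(self.free_names, x_est):
            out[name] = self.priors[name].to_native(value)
        return out

    def _loglik_arrays(self, muhat1, pihat2, muhat3, zeta: float | None) -> float:
        resp = self.response
        y, obs = self._y, self._obs
        if resp.family == "unit_square_sigmoid":
            lp1, lp0 = _unit_square_log_p1(muhat1, zeta)
        elif resp.family == "volatility_temperature":
            lp1, lp0 = _unit_square_log_p1(muhat1, np.exp(-muhat3))
        elif resp.family == "precision_temperature":
            lp1, lp0 = _unit_square_log_p1(muhat1, pihat2)
        else:  # bandit_softmax
            if self.series.r_a is None or self.series.r_b is None:
                raise ValueError("bandit_softmax needs reward columns r_a/r_b")
            drive = self.series.r_b * muhat1 - self.series.r_a * (1.0 - muhat1)
            if resp.sign_flipped_softmax:
                drive = -drive
            z = zeta * drive
            lp1 = -np.logaddexp(0.0, -z)
            lp0 = -np.logaddexp(0.0, z)
        lp1 = np.maximum(lp1, math.log(EPS))
        lp0 = np.maximum(lp0, math.log(EPS))
        return float(np.sum(np.where(y[obs] == 1.0, lp1[obs], lp0[obs])))

    def __call__(self, x_est: np.ndarray, sentinel: bool = True) -> float:
        self.n_calls += 1
        nat = self.natives(np.asarray(x_est, dtype=float))
        zeta = nat.get("zeta")
        try:
            if self._fast_ok:
                ok, viol, muhat1, pihat2, muhat3, *_ = _fast.filter_binary3(
                    self.series.u, self.series.t, nat["kappa"], nat["omega"],
                    nat["theta"], nat["mu2_0"], nat["sigma2_0"], nat["mu3_0"],
                    nat["sigma3_0"])
                if not ok:
                    raise ModelViolationError("filter breakdown", trial=viol)
            else:
                traj = self._filter(nat)
                muhat1 = traj.mu_hat[:, 0]
                pihat2 = traj.pi_hat[:, 1]
                muhat3 = traj.mu_hat[:, 2]
            loglik = self._loglik_arrays(muhat1, pihat2, muhat3, zeta)
        except (HGFError, ValueError, ZeroDivisionError, OverflowError):
            # out-of-domain natives (underflowed transforms) or filter
            # breakdown: the optimizer is told to retreat
            if sentinel:
                return SENTINEL
            raise
        return loglik + log_prior(
            dict(zip(self.free_names, x_est)), self.priors)

    def _filter(self, nat: dict[str, float]) -> Trajectory:
        params = BinaryHGFParams(kappa=nat["kappa"], omega=nat["omega"],
                                 theta=nat["theta"])
        init = InitialBelief(mu0=(nat["mu2_0"], nat["mu3_0"]),
                             sigma0=(nat["sigma2_0"], nat["sigma3_0"]))
        return filter_sequence_binary(self.series, params, self.input_model, init)

    def trajectory(self, nat: dict[str, float]) -> Trajectory:
        return self._filter(nat)

    def response_at(self, nat: dict[str, float]) -> ResponseModelSpec:
        if self.response.has_zeta:
            return self.response.with_zeta(nat["zeta"])
        return self.response


def objective_Z(xi_est: dict[str, float], series: TrialSeries,
                response: ResponseModelSpec, priors: dict[str, Prior],
                input_model: BinaryInputModel | None = None,
                sentinel: bool = False) -> float:
    """Log-joint Z of responses and parameters, given inputs.

    ``xi_est`` maps each *free* parameter name to its estimation-space
    value; fixed parameters are taken from the priors and cannot be
    overridden here.  With ``sentinel=True`` a model violation returns a
    large negative value instead of raising (the convention used during
    optimization, so that search retreats from broken regions).
    """
    obj = _Objective(series, response, priors, input_model)
    unknown = set(xi_est) - set(obj.free_names)
    if unknown:
        raise ValueError(
            f"{sorted(unknown)} are not free parameters (fixed parameters are immutable)")
    x = np.array([xi_est[n] for n in obj.free_names])
    return obj(x, sentinel=sentinel)


@dataclass
class FitResult:
    """MAP fit of the HGF/decision-model combination."""

    xi_map: dict[str, float]           # native space, all parameters
    xi_map_est: dict[str, float]       # estimation space, free parameters
    objective: float                   # Z at the MAP
    free_names: list[str]
    trajectory: Trajectory
    n_function_evals: int
    converged: bool
    log_evidence: float | None = None
    diagnostics: dict = field(default_factory=dict)


def fit_map(series: TrialSeries, response: ResponseModelSpec,
            priors: dict[str, Prior], optimizer: str = "simplex",
            seed: int = 0, restarts: int = 3,
            input_model: BinaryInputModel | None = None,
            mcmc_kwargs: dict | None = None) -> FitResult:
    """MAP estimation by Nelder-Mead simplex search in estimation space.

    The search starts from the prior means with ``restarts`` additional
    seeded starts jittered by half a prior standard deviation, keeping
    the best optimum (optimizer "simplex").  Optimizer "mcmc_map" runs a
    Metropolis-within-Gibbs chain and polishes the best sample with a
    simplex run.  Deterministic given (seed, data, priors).
    """
    obj = _Objective(series, response, priors, input_model)
    d = len(obj.free_names)
    if d == 0:
        x_best = np.empty(0)
        z_best = obj(x_best, sentinel=False)
        converged = True
        diagnostics = {"starts": []}
    elif optimizer == "simplex":
        rng = np.random.default_rng(seed)
        starts = [obj.x0]
        sd = obj.prior_sd
        for _ in range(restarts):
            starts.append(obj.x0 + 0.5 * sd * rng.standard_normal(d))
        best = None
        per_start = []
        for x0 in starts:
            res = optimize.minimize(lambda x: -obj(x), x0, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-6,
                                             "maxfev": 400 * d})
            per_start.append((-res.fun, bool(res.success)))
            if best is None or -res.fun > -best.fun:
                best = res
        x_best, z_best = best.x, -best.fun
        converged = any(s for _, s in per_start)
        diagnostics = {"starts": per_start}
        if not converged:
            warnings.warn("simplex search did not converge from any start; "
                          "returning the best point found", RuntimeWarning)
    elif optimizer == "mcmc_map":
        kw = dict(chain_length=20_000, burn_in=2_000)
        kw.update(mcmc_kwargs or {})
        mcmc = sample_posterior_mcmc(series, response, priors, seed=seed,
                                     input_model=input_model, **kw)
        i_best = int(np.argmax(mcmc.log_posterior))
        res = optimize.minimize(lambda x: -obj(x), mcmc.samples[i_best],
                                method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxfev": 400 * d})
        x_best, z_best = res.x, -res.fun
        converged = bool(res.success)
        diagnostics = {"mcmc_acceptance": mcmc.acceptance}
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    if z_best <= SENTINEL:
        raise ModelViolationError("objective is undefined everywhere explored")
    nat = obj.natives(x_best)
    return FitResult(
        xi_map=nat,
        xi_map_est=dict(zip(obj.free_names, (float(v) for v in x_best))),
        objective=float(z_best),
        free_names=list(obj.free_names),
        trajectory=obj.trajectory(nat),
        n_function_evals=obj.n_calls,
        converged=converged,
        diagnostics=diagnostics,
    )


def laplace_from_callable(f, x_map: np.ndarray, step: float = 1e-4) -> float:
    """Laplace log-evidence of a callable log-joint at its maximum.

    F = f(x*) + d/2 ln(2 pi) - 1/2 ln det H with H the negative Hessian
    of f at x*, estimated by central finite differences with the given
    step.  A non-positive-definite H is repaired to the nearest positive
    definite matrix (eigenvalue clipping) with a warning.
    """
    x_map = np.asarray(x_map, dtype=float)
    d = x_map.size
    f0 = f(x_map)
    if d == 0:
        return float(f0)
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x_map + ei) - 2.0 * f0 + f(x_map - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x_map + ei + ej) - f(x_map + ei - ej)
                - f(x_map - ei + ej) + f(x_map - ei - ej)
            ) / (4.0 * step**2)
    negH = -H
    eigval, eigvec = np.linalg.eigh(negH)
    if np.any(eigval <= 0):
        floor = 1e-8 * max(float(np.max(np.abs(eigval))), 1.0)
        warnings.warn(
            f"negative Hessian at the optimum is not positive definite "
            f"(min eigenvalue {eigval.min():.3g}); repaired by clipping "
            f"eigenvalues at {floor:.3g}", RuntimeWarning)
        eigval = np.clip(eigval, floor, None)
    logdet = float(np.sum(np.log(eigval)))
    return float(f0) + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet


def laplace_log_evidence(fit: FitResult, series: TrialSeries,
                         response: ResponseModelSpec, priors: dict[str, Prior],
                         input_model: BinaryInputModel | None = None,
                         step: float = 1e-4) -> float:
    """Laplace approximation to the log model evidence at a MAP fit.

    Computed in estimation space where the priors are Gaussian.  Stores
    the value on ``fit.log_evidence`` and returns it.
    """
    obj = _Objective(series, response, priors, input_model)
    x_map = np.array([fit.xi_map_est[n] for n in obj.free_names])
    F = laplace_from_callable(lambda x: obj(x, sentinel=True), x_map, step=step)
    fit.log_evidence = F
    return F


def bayes_factor(F_a: float, F_b: float) -> float:
    """Bayes factor of model b over model a from log evidences: exp(F_b - F_a)."""
    return math.exp(F_b - F_a)


def metropolis_gibbs(logp, x0: np.ndarray, scales: np.ndarray, chain_length: int,
                     burn_in: int, rng: np.random.Generator,
                     adapt: bool = True,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component-wise Metropolis sampler (one Gaussian step per coordinate).

    During burn-in the per-coordinate proposal scale is re-tuned every
    100 samples (widened above 50% recent acceptance, narrowed below
    20%) and frozen afterwards, so the post-burn-in chain is a valid
    fixed-kernel Markov chain.  Returns (samples after burn-in,
    log-posterior per kept sample, post-burn-in acceptance rate per
    coordinate).
    """
    if chain_length <= burn_in:
        raise ValueError("chain_length must exceed burn_in")
    x = np.asarray(x0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float).copy()
    d = x.size
    lp = logp(x)
    n_kept = chain_length - burn_in
    kept = np.empty((n_kept, d))
    kept_lp = np.empty(n_kept)
    accepted = np.zeros(d)
    window = np.zeros(d)
    for s in range(chain_length):
        for i in range(d):
            prop = x[i] + scales[i] * rng.standard_normal()
            old = x[i]
            x[i] = prop
            lp_prop = logp(x)
            if math.log(rng.random()) < lp_prop - lp:
                lp = lp_prop
                if s >= burn_in:
                    accepted[i] += 1
                else:
                    window[i] += 1
            else:
                x[i] = old
        if adapt and s < burn_in and (s + 1) % 100 == 0:
            rate = window / 100.0
            scales[rate > 0.5] *= 1.5
            scales[rate < 0.2] /= 1.5
            window[:] = 0.0
        if s >= burn_in:
            kept[s - burn_in] = x
            kept_lp[s - burn_in] = lp
    return kept, kept_lp, accepted / n_kept


@dataclass
class MCMCResult:
    """Posterior samples from Metropolis-within-Gibbs."""

    free_names: list[str]
    samples: np.ndarray          # estimation space, (n_kept, d)
    samples_native: np.ndarray   # native space, (n_kept, d)
    log_posterior: np.ndarray
    acceptance: dict[str, float]
    pci95: dict[str, tuple[float, float]]  # native space


def sample_posterior_mcmc(series: TrialSeries, response: ResponseModelSpec,
                          priors: dict[str, Prior], chain_length: int = 20_000,
                          burn_in: int = 2_000, seed: int = 0,
                          proposal_scales: np.ndarray | None = None,
                          start: dict[str, float] | None = None,
                          input_model: BinaryInputModel | None = None) -> MCMCResult:
    """Posterior sampling of the free parameters in estimation space.

    One chain; each sample updates every free parameter with a
    one-dimensional Metropolis step.  Proposal standard deviations
    default to 0.4 prior standard deviations; acceptance rates outside
    [0.1, 0.7] trigger a tuning warning.  The 95% posterior central
    interval (PCI) per parameter — excluding 2.5% of mass on either side
    — is reported in native space.
    """
    obj = _Objective(series, response, priors, input_model)
    d = len(obj.free_names)
    if d == 0:
        raise ValueError("no free parameters to sample")
    if proposal_scales is None:
        proposal_scales = 0.4 * obj.prior_sd
    x0 = obj.x0 if start is None else np.array([start[n] for n in obj.free_names])
    rng = np.random.default_rng(seed)
    kept, kept_lp, acc = metropolis_gibbs(
        lambda x: obj(x, sentinel=True), x0, proposal_scales,
        chain_length, burn_in, rng)
    acceptance = dict(zip(obj.free_names, (float(a) for a in acc)))
    for name, a in acceptance.items():
        if not 0.1 <= a <= 0.7:
            warnings.warn(
                f"MCMC acceptance rate for {name} is {a:.2f}, outside [0.1, 0.7]; "
                f"consider tuning proposal_scales", RuntimeWarning)
    native = np.empty_like(kept)
    for j, name in enumerate(obj.free_names):
        prior = priors[name]
        native[:, j] = [prior.to_native(v) for v in kept[:, j]]
    pci = {
        name: (float(np.percentile(native[:, j], 2.5)),
               float(np.percentile(native[:, j], 97.5)))
        for j, name in enumerate(obj.free_names)
    }
    return MCMCResult(
        free_names=list(obj.free_names), samples=kept, samples_native=native,
        log_posterior=kept_lp, acceptance=acceptance, pci95=pci,
    )


def check_identifiability(response: ResponseModelSpec,
                          priors: dict[str, Prior]) -> list[str]:
    """Warn about overparameterized level-3 settings.

    When mu_3 does not enter the response model (constant-zeta sigmoid,
    bandit softmax), behavior fixes neither the origin nor the scale of
    x_3, so at least two of {mu3_0, kappa, omega} should be fixed.  The
    dynamic-temperature models make mu_3 observable, so no restriction
    applies.  Returns the warning messages (also emitted via
    ``warnings.warn``).
    """
    messages: list[str] = []
    mu3_in_response = response.family in ("volatility_temperature",
                                          "precision_temperature")
    if not mu3_in_response:
        trio = ("mu3_0", "kappa", "omega")
        n_fixed = sum(1 for n in trio if n in priors and priors[n].fixed)
        if n_fixed < 2:
            messages.append(
                "mu_3 does not enter the response model; fix at least two of "
                "{mu3_0, kappa, omega} to choose an origin and scale for x_3 "
                f"(currently {n_fixed} fixed)")
    for msg in messages:
        warnings.warn(msg, UserWarning)
    return messages
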