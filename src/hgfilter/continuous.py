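"""n-level continuous Hierarchical Gaussian Filter.

The generative model is a hierarchy of coupled Gaussian random walks

    x_i^(k) ~ N(x_i^(k-1), t^(k) * f_i(x_{i+1}^(k))),    i = 1..n-1
    x_n^(k) ~ N(x_n^(k-1), t^(k) * theta)

with volatility coupling f_i(x_{i+1}) = exp(kappa_i * x_{i+1} + omega_i)
and a Gaussian emission u^(k) ~ N(x_1^(k), 1/pi_hat_u).  kappa_i scales
the phasic (state-dependent) log-volatility of level i, omega_i is its
tonic part, and theta is the constant step variance at the top.

Variational inversion under Gaussian posteriors N(mu_i, 1/pi_i) gives the
one-step update equations implemented here.  Per trial, predictions are
formed from the previous trial's posteriors,

    mu_hat_i = mu_i(k-1)
    v_i      = t * exp(kappa_i * mu_{i+1}(k-1) + omega_i)   (v_n = t*theta)
    pi_hat_i = 1 / (sigma_i(k-1) + v_i),

the first level assimilates the input through a value prediction error
(VAPE) delta_u = u - mu_hat_1, and every higher level assimilates the
volatility prediction error (VOPE) of the level below,

    delta_i = (sigma_i(k) + (mu_i(k) - mu_hat_i)^2) / (sigma_i(k-1) + v_i) - 1,

via precision-weighted updates (see :func:`update_higher_level`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hgfilter.exceptions import InputFormatError, ModelViolationError

__all__ = [
    "PerceptualParams",
    "ContinuousInputModel",
    "InitialBelief",
    "BeliefState",
    "PredictionSet",
    "TrialSeries",
    "Trajectory",
    "predict_level",
    "volatility_prediction_error",
    "update_first_level_continuous",
    "update_higher_level",
    "filter_sequence",
    "simulate_generative",
    "learning_rate_diagnostics",
]

# exp() overflows at ~709.78 for float64; beyond this the coupling is
# outside the model's domain of validity anyway.
_EXP_ARG_MAX = 700.0


def _coupling_variance(t: float, kappa: float, mu_above: float, omega: float,
                       trial: int | None = None, level: int | None = None) -> float:
    """t * exp(kappa*mu_above + omega) with an overflow guard."""
    arg = kappa * mu_above + omega
    if not math.isfinite(arg) or arg > _EXP_ARG_MAX:
        raise ModelViolationError(
            f"volatility coupling exp({arg:.3g}) is not finite", trial=trial, level=level
        )
    return t * math.exp(arg)


@dataclass(frozen=True)
class PerceptualParams:
    """Perceptual parameters chi of an n-level continuous HGF.

    Parameters
    ----------
    kappa
        Coupling strengths kappa_i >= 0 for levels i = 1..n-1.  The sign
        convention kappa > 0 makes the volatility of level i increase
        with x_{i+1} (flipping kappa's sign is equivalent to flipping
        x_{i+1}); kappa_i = 0 decouples level i+1, freezing its belief
        except for its own prediction step.
    omega
        Tonic log-volatilities omega_i, i = 1..n-1 (any real value).
    theta
        Constant step variance of the top-level random walk (> 0).
    """

    kappa: tuple[float, ...]
    omega: tuple[float, ...]
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "kappa", tuple(float(k) for k in np.atleast_1d(self.kappa)))
        object.__setattr__(self, "omega", tuple(float(w) for w in np.atleast_1d(self.omega)))
        if len(self.kappa) != len(self.omega):
            raise ValueError("kappa and omega must have equal length (n_levels - 1)")
        if len(self.kappa) < 1:
            raise ValueError("need at least a two-level hierarchy")
        if any(k < 0 for k in self.kappa):
            raise ValueError("kappa must be non-negative (positive by convention)")
        if not self.theta > 0:
            raise ValueError("theta must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.kappa) + 1


@dataclass(frozen=True)
class ContinuousInputModel:
    """Gaussian input channel u ~ N(x_1, 1/pi_hat_u)."""

    pi_hat_u: float

    def __post_init__(self):
        if self.pi_hat_u < 0:
            raise ValueError("pi_hat_u must be non-negative")


@dataclass(frozen=True)
class InitialBelief:
    """Initial representations lambda(0): means mu_i(0) and variances sigma_i(0)."""

    mu0: tuple[float, ...]
    sigma0: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "mu0", tuple(float(m) for m in np.atleast_1d(self.mu0)))
        object.__setattr__(self, "sigma0", tuple(float(s) for s in np.atleast_1d(self.sigma0)))
        if len(self.mu0) != len(self.sigma0):
            raise ValueError("mu0 and sigma0 must have equal length")
        if any(s <= 0 for s in self.sigma0):
            raise ValueError("all sigma0 must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.mu0)


@dataclass
class BeliefState:
    """Posterior means and precisions per level after one trial."""

    mu: np.ndarray
    pi: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return 1.0 / self.pi

    @classmethod
    def from_initial(cls, init: InitialBelief) -> "BeliefState":
        return cls(mu=np.array(init.mu0, dtype=float),
                   pi=1.0 / np.array(init.sigma0, dtype=float))


@dataclass
class PredictionSet:
    """Per-trial predictions and prediction errors.

    mu_hat/pi_hat are the predictive means/precisions, v the environmental
    uncertainty added by possible movement of the state itself, delta the
    VOPEs and delta_u the input VAPE.
    """

    mu_hat: np.ndarray
    pi_hat: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    delta_u: float = math.nan


@dataclass
class TrialSeries:
    """Trial-wise inputs u, optional binary responses y, intervals t.

    Missing responses are NaN.  Intervals default to 1 (regular sampling).
    Optional per-trial reward columns r_a/r_b support the bandit decision
    model.
    """

    u: np.ndarray
    y: np.ndarray | None = None
    t: np.ndarray | None = None
    r_a: np.ndarray | None = None
    r_b: np.ndarray | None = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 1 or self.u.size < 1:
            raise InputFormatError("u must be a one-dimensional series with K >= 1")
        K = self.u.size
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (K,):
                raise InputFormatError("y must have the same length as u")
            observed = self.y[~np.isnan(self.y)]
            if not np.isin(observed, (0.0, 1.0)).all():
                raise InputFormatError("responses y must be 0 or 1 (NaN = missing)")
        if self.t is None:
            self.t = np.ones(K)
        else:
            self.t = np.asarray(self.t, dtype=float)
            if self.t.shape != (K,):
                raise InputFormatError("t must have the same length as u")
            if not (self.t > 0).all():
                raise InputFormatError("all inter-trial intervals t must be positive")
        for name in ("r_a", "r_b"):
            r = getattr(self, name)
            if r is not None:
                r = np.asarray(r, dtype=float)
                if r.shape != (K,):
                    raise InputFormatError(f"{name} must have the same length as u")
                setattr(self, name, r)

    @property
    def K(self) -> int:
        return self.u.size


@dataclass
class Trajectory:
    """Filtered belief trajectory over K trials and n levels.

    All arrays are (K, n) except delta_u (K,).  Row k holds the trial-k
    predictions (derived from trial k-1 posteriors only) and the trial-k
    posteriors.  psi holds the learning-rate diagnostics of
    :func:`learning_rate_diagnostics`.
    """

    mu_hat: np.ndarray
    pi_hat: np.ndarray
    v: np.ndarray
    mu: np.ndarray
    pi: np.ndarray
    delta: np.ndarray
    delta_u: np.ndarray
    psi: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def n_levels(self) -> int:
        return self.mu.shape[1]

    @property
    def sigma(self) -> np.ndarray:
        return 1.0 / self.pi

    def final_state(self) -> BeliefState:
        return BeliefState(mu=self.mu[-1].copy(), pi=self.pi[-1].copy())


def predict_level(belief_prev: BeliefState, params: PerceptualParams, t: float,
                  i: int, trial: int | None = None) -> tuple[float, float, float]:
    """Predictive mean, precision and environmental uncertainty at level i.

    ``i`` is 1-based.  Irregular sampling enters only through t, which
    scales the step variance of every random walk (mean squared
    displacement of a random walk is proportional to elapsed time).

    Returns (mu_hat_i, pi_hat_i, v_i).
    """
    n = params.n_levels
    if not 1 <= i <= n:
        raise ValueError(f"level index {i} outside 1..{n}")
    idx = i - 1
    if i == n:
        v = t * params.theta
    else:
        v = _coupling_variance(t, params.kappa[idx], belief_prev.mu[idx + 1],
                               params.omega[idx], trial=trial, level=i)
    mu_hat = belief_prev.mu[idx]
    sigma_prev = 1.0 / belief_prev.pi[idx]
    pi_hat = 1.0 / (sigma_prev + v)
    return mu_hat, pi_hat, v


def volatility_prediction_error(mu_post: float, sigma_post: float, mu_hat: float,
                                sigma_prev: float, v: float,
                                trial: int | None = None,
                                level: int | None = None) -> float:
    """VOPE: observed over predicted uncertainty at a level, minus one.

    delta = (sigma(k) + (mu(k) - mu_hat)^2) / (sigma(k-1) + v) - 1

    The numerator is observed uncertainty (posterior variance plus squared
    surprise about the mean), the denominator predicted uncertainty
    (informational sigma(k-1) plus environmental v).  By construction
    delta >= -1.
    """
    denom = sigma_prev + v
    if denom <= 0:
        raise ModelViolationError(
            "predicted uncertainty (sigma + v) is not positive", trial=trial, level=level
        )
    return (sigma_post + (mu_post - mu_hat) ** 2) / denom - 1.0


def update_first_level_continuous(mu_hat_1: float, pi_hat_1: float,
                                  input_model: ContinuousInputModel,
                                  u: float) -> tuple[float, float, float]:
    """Assimilate a continuous input at level 1.

    This is exactly the conjugate Gaussian update with prior
    N(mu_hat_1, 1/pi_hat_1) and likelihood precision pi_hat_u:

        delta_u = u - mu_hat_1
        pi_1    = pi_hat_1 + pi_hat_u
        mu_1    = mu_hat_1 + pi_hat_u / pi_1 * delta_u

    Returns (mu_1, pi_1, delta_u).
    """
    if not math.isfinite(u):
        raise InputFormatError(f"non-finite input u = {u!r}")
    delta_u = u - mu_hat_1
    pi_1 = pi_hat_1 + input_model.pi_hat_u
    mu_1 = mu_hat_1 + input_model.pi_hat_u / pi_1 * delta_u
    return mu_1, pi_1, delta_u


def update_higher_level(mu_hat_i: float, pi_hat_i: float, delta_below: float,
                        kappa_below: float, v_below: float, pi_hat_below: float,
                        pi_below_prev: float, trial: int | None = None,
                        level: int | None = None) -> tuple[float, float]:
    """Assimilate the VOPE of the level below at level i >= 2.

    Precision first,

        pi_i = pi_hat_i + 1/2 (kappa v pi_hat_below)^2
               * (1 + (1 - 1/(v * pi_below_prev)) * delta),

    then the precision-weighted mean update

        mu_i = mu_hat_i + 1/2 kappa v pi_hat_below / pi_i * delta.

    ``pi_below_prev`` is the *previous-trial* posterior precision at the
    level below, while ``delta_below`` is built from the current-trial
    posterior there; the equations mix time indices this way.  A
    non-positive resulting precision means the agent would know "less
    than nothing" and raises :class:`ModelViolationError`.
    """
    vp = v_below * pi_below_prev
    if vp <= 0 or not math.isfinite(vp):
        raise ModelViolationError(
            f"environmental-uncertainty weight v*pi = {vp:.3g} is outside (0, inf)",
            trial=trial, level=level)
    w = kappa_below * v_below * pi_hat_below
    pi_i = pi_hat_i + 0.5 * w * w * (
        1.0 + (1.0 - 1.0 / vp) * delta_below
    )
    if not pi_i > 0 or not math.isfinite(pi_i):
        raise ModelViolationError(
            f"posterior precision pushed to {pi_i:.3g}", trial=trial, level=level
        )
    mu_i = mu_hat_i + 0.5 * kappa_below * v_below * pi_hat_below / pi_i * delta_below
    return mu_i, pi_i


def _filter_one_trial(belief_prev: BeliefState, params: PerceptualParams,
                      input_model: ContinuousInputModel, u: float, t: float,
                      trial: int | None = None) -> tuple[BeliefState, PredictionSet]:
    """One filtering step: predict all levels, update bottom-up."""
    n = params.n_levels
    mu_hat = np.empty(n)
    pi_hat = np.empty(n)
    v = np.empty(n)
    for i in range(1, n + 1):
        mu_hat[i - 1], pi_hat[i - 1], v[i - 1] = predict_level(
            belief_prev, params, t, i, trial=trial)

    mu = np.empty(n)
    pi = np.empty(n)
    delta = np.full(n, math.nan)

    if math.isnan(u):
        # missing input: beliefs diffuse through the prediction step only
        mu[:] = mu_hat
        pi[:] = pi_hat
        return BeliefState(mu=mu, pi=pi), PredictionSet(mu_hat, pi_hat, v, delta)

    mu[0], pi[0], delta_u = update_first_level_continuous(
        mu_hat[0], pi_hat[0], input_model, u)

    for i in range(2, n + 1):
        j = i - 2  # array index of the level below
        delta[j] = volatility_prediction_error(
            mu[j], 1.0 / pi[j], mu_hat[j], 1.0 / belief_prev.pi[j], v[j],
            trial=trial, level=i - 1)
        mu[i - 1], pi[i - 1] = update_higher_level(
            mu_hat[i - 1], pi_hat[i - 1], delta[j], params.kappa[j], v[j],
            pi_hat[j], belief_prev.pi[j], trial=trial, level=i)

    return BeliefState(mu=mu, pi=pi), PredictionSet(mu_hat, pi_hat, v, delta, delta_u)


def filter_sequence(series: TrialSeries, params: PerceptualParams,
                    input_model: ContinuousInputModel,
                    init: InitialBelief) -> Trajectory:
    """Filter a continuous input series through an n-level HGF.

    Per trial: predictions for all levels from the previous posteriors,
    then the level-1 VAPE update, then a bottom-up sweep of VOPE updates
    for levels 2..n.  Trial k never sees inputs beyond u^(k).
    """
    n = params.n_levels
    if init.n_levels != n:
        raise ValueError("initial belief and parameters disagree on the number of levels")
    K = series.K
    traj = Trajectory(
        mu_hat=np.empty((K, n)), pi_hat=np.empty((K, n)), v=np.empty((K, n)),
        mu=np.empty((K, n)), pi=np.empty((K, n)), delta=np.empty((K, n)),
        delta_u=np.empty(K),
    )
    state = BeliefState.from_initial(init)
    for k in range(K):
        state, pred = _filter_one_trial(
            state, params, input_model, series.u[k], series.t[k], trial=k + 1)
        traj.mu_hat[k] = pred.mu_hat
        traj.pi_hat[k] = pred.pi_hat
        traj.v[k] = pred.v
        traj.delta[k] = pred.delta
        traj.delta_u[k] = pred.delta_u
        traj.mu[k] = state.mu
        traj.pi[k] = state.pi
    traj.psi = learning_rate_diagnostics(traj)
    return traj


def simulate_generative(params: PerceptualParams, input_model: ContinuousInputModel,
                        init: InitialBelief, K: int, seed: int,
                        t_series: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent random walks and noisy inputs from the generative model.

    States start at x_i^(0) = mu_i(0) and evolve top-down per step (the
    step variance of level i depends on x_{i+1} at the *current* step):

        x_n^(k)  ~ N(x_n^(k-1), t * theta)
        x_i^(k)  ~ N(x_i^(k-1), t * exp(kappa_i x_{i+1}^(k) + omega_i))
        u^(k)    ~ N(x_1^(k), 1/pi_hat_u)

    Returns (x, u) with x of shape (K, n_levels).
    """
    n = params.n_levels
    if init.n_levels != n:
        raise ValueError("initial belief and parameters disagree on the number of levels")
    rng = np.random.default_rng(seed)
    if t_series is None:
        t_series = np.ones(K)
    else:
        t_series = np.asarray(t_series, dtype=float)
        if t_series.shape != (K,):
            raise ValueError("t_series must have length K")
    x = np.empty((K, n))
    prev = np.array(init.mu0, dtype=float)
    for k in range(K):
        t = t_series[k]
        x[k, n - 1] = prev[n - 1] + math.sqrt(t * params.theta) * rng.standard_normal()
        for i in range(n - 1, 0, -1):  # level i, 1-based, top-down
            var = _coupling_variance(t, params.kappa[i - 1], x[k, i], params.omega[i - 1])
            x[k, i - 1] = prev[i - 1] + math.sqrt(var) * rng.standard_normal()
        prev = x[k]
    if input_model.pi_hat_u > 0:
        u = x[:, 0] + rng.standard_normal(K) / math.sqrt(input_model.pi_hat_u)
    else:
        u = x[:, 0].copy()
    return x, u


def learning_rate_diagnostics(trajectory: Trajectory) -> np.ndarray:
    """Per-trial precision weights psi acting as dynamic learning rates.

    psi_i = pi_hat_{i-1} / pi_i for i >= 2 (the weight on the VOPE from
    the level below) and psi_1 = 1/pi_1 = sigma_1 at the lowest level
    carrying a Gaussian walk.  In the three-level binary model these are
    the familiar psi_3 = pi_hat_2/pi_3 and psi_2 = 1/pi_2.
    """
    psi = np.empty_like(trajectory.pi)
    psi[:, 0] = 1.0 / trajectory.pi[:, 0]
    psi[:, 1:] = trajectory.pi_hat[:, :-1] / trajectory.pi[:, 1:]
    return psi
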