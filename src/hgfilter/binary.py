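"""Hierarchical Gaussian Filter for binary outcomes.

The lowest state x_1 is binary; x_2 is its tendency on the logit scale,
p(x_1 = 1 | x_2) = s(x_2) with the logistic sigmoid s.  x_3 (and any
levels above) are continuous volatility states exactly as in
:mod:`hgfilter.continuous`; the only coupled level below the top is
level 2, so we write kappa = kappa_2 and omega = omega_2.

Two input channels are supported.  In *noiseless* mode the input is the
state itself, u = x_1 in {0, 1}.  In *noisy* mode the input is Gaussian
around a level that depends on the state,

    u ~ N(eta_1, 1/pi_hat_u)  if x_1 = 1,
    u ~ N(eta_0, 1/pi_hat_u)  if x_1 = 0,

and the posterior over x_1 is obtained by Bayes' rule over the
two-component mixture (:func:`infer_binary_state`).

The level-2 updates take the specific form

    mu_hat_1 = s(mu_2(k-1)),  pi_hat_1 = 1/(mu_hat_1 (1 - mu_hat_1))
    pi_hat_2 = 1/(sigma_2(k-1) + t exp(kappa mu_3(k-1) + omega))
    delta_1  = mu_1 - mu_hat_1
    pi_2     = pi_hat_2 + 1/pi_hat_1
    mu_2     = mu_2(k-1) + delta_1 / pi_2

(the Bernoulli variance replaces the Gaussian predictive variance at
level 1); level 3 and above use the generic VOPE updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hgfilter.continuous import (
    InitialBelief,
    Trajectory,
    TrialSeries,
    _coupling_variance,
    update_higher_level,
    volatility_prediction_error,
)
from hgfilter.exceptions import InputFormatError, RenormalizationError

__all__ = [
    "BinaryInputModel",
    "BinaryHGFParams",
    "sigmoid",
    "predict_first_level_binary",
    "infer_binary_state",
    "update_second_level_binary",
    "filter_sequence_binary",
    "simulate_binary_generative",
    "binary_learning_rates",
]


def sigmoid(x):
    """Logistic sigmoid s(x) = 1/(1 + exp(-x)).

    Saturates in float64 for |x| > ~37; callers that feed the result into
    logs clamp to (0, 1) themselves.  Accepts scalars or arrays.
    """
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class BinaryInputModel:
    """Input channel of the binary HGF.

    mode "noiseless": u is x_1 itself (values must be exactly 0 or 1).
    mode "noisy": Gaussian emission around eta_1/eta_0 with precision
    pi_hat_u.
    """

    mode: str = "noiseless"
    eta1: float = 1.0
    eta0: float = 0.0
    pi_hat_u: float = 1.0

    def __post_init__(self):
        if self.mode not in ("noiseless", "noisy"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "noisy":
            if self.eta1 == self.eta0:
                raise ValueError("noisy mode requires eta1 != eta0")
            if not self.pi_hat_u > 0:
                raise ValueError("noisy mode requires pi_hat_u > 0")


@dataclass(frozen=True)
class BinaryHGFParams:
    """Parameters of the binary HGF.

    ``kappa``/``omega`` couple level 2 to level 3; ``theta`` is the
    top-level step variance.  For hierarchies with more than three
    levels, ``upper_kappa``/``upper_omega`` couple level i to i+1 for
    i = 3..n-1 (rarely needed; the classic model has n = 3).
    """

    kappa: float
    omega: float
    theta: float
    upper_kappa: tuple[float, ...] = ()
    upper_omega: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative (positive by convention)")
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if len(self.upper_kappa) != len(self.upper_omega):
            raise ValueError("upper_kappa and upper_omega must have equal length")
        if any(k < 0 for k in self.upper_kappa):
            raise ValueError("all upper_kappa must be non-negative")

    @property
    def n_levels(self) -> int:
        return 3 + len(self.upper_kappa)

    def kappa_at(self, i: int) -> float:
        """Coupling strength of level i to level i+1 (i >= 2)."""
        return self.kappa if i == 2 else self.upper_kappa[i - 3]

    def omega_at(self, i: int) -> float:
        return self.omega if i == 2 else self.upper_omega[i - 3]


def predict_first_level_binary(mu2_prev: float) -> tuple[float, float]:
    """Predictive outcome probability and its Bernoulli precision.

    mu_hat_1 = s(mu_2(k-1)); pi_hat_1 = 1/(mu_hat_1 (1 - mu_hat_1)).

    mu_hat_1 is kept strictly inside (0, 1): float64 saturation of the
    sigmoid at |mu_2| > ~37 is clipped at 1e-15 from either boundary so
    that pi_hat_1 stays finite.
    """
    mu_hat_1 = 0.5 * (1.0 + math.tanh(0.5 * mu2_prev))
    mu_hat_1 = min(max(mu_hat_1, 1e-15), 1.0 - 1e-15)
    pi_hat_1 = 1.0 / (mu_hat_1 * (1.0 - mu_hat_1))
    return mu_hat_1, pi_hat_1


def infer_binary_state(mu_hat_1: float, u: float, input_model: BinaryInputModel) -> float:
    """Posterior probability mu_1 that x_1 = 1 given input u.

    Noiseless mode passes u through (after validating it is 0 or 1).
    Noisy mode applies Bayes' rule to the two-component Gaussian mixture:

        mu_1 = mu_hat_1 N(u; eta_1, 1/pi_hat_u)
               / (mu_hat_1 N(u; eta_1, .) + (1 - mu_hat_1) N(u; eta_0, .))

    where the shared normalization constants cancel.
    """
    if input_model.mode == "noiseless":
        if u not in (0.0, 1.0):
            raise InputFormatError(
                f"noiseless binary input must be 0 or 1, got {u!r}")
        return float(u)
    w1 = mu_hat_1 * math.exp(-0.5 * input_model.pi_hat_u * (u - input_model.eta1) ** 2)
    w0 = (1.0 - mu_hat_1) * math.exp(-0.5 * input_model.pi_hat_u * (u - input_model.eta0) ** 2)
    total = w1 + w0
    if total == 0.0:
        raise RenormalizationError(
            f"both mixture components underflowed at u = {u:.6g} "
            f"(mu_hat_1 = {mu_hat_1:.6g}, eta1 = {input_model.eta1}, "
            f"eta0 = {input_model.eta0}, pi_hat_u = {input_model.pi_hat_u})")
    return w1 / total


def update_second_level_binary(mu2_prev: float, sigma2_prev: float, mu3_prev: float,
                               params: BinaryHGFParams, t: float, mu1: float,
                               trial: int | None = None,
                               ) -> tuple[float, float, float, float, float, float]:
    """Level-2 update of the binary HGF.

    Returns (mu_2, pi_2, delta_1, mu_hat_1, pi_hat_1, pi_hat_2).
    """
    mu_hat_1, pi_hat_1 = predict_first_level_binary(mu2_prev)
    v2 = _coupling_variance(t, params.kappa, mu3_prev, params.omega, trial=trial, level=2)
    pi_hat_2 = 1.0 / (sigma2_prev + v2)
    delta_1 = mu1 - mu_hat_1
    pi_2 = pi_hat_2 + 1.0 / pi_hat_1
    mu_2 = mu2_prev + delta_1 / pi_2
    return mu_2, pi_2, delta_1, mu_hat_1, pi_hat_1, pi_hat_2


def filter_sequence_binary(series: TrialSeries, params: BinaryHGFParams,
                           input_model: BinaryInputModel,
                           init: InitialBelief) -> Trajectory:
    """Filter a binary-outcome series through the n-level binary HGF.

    ``init`` specifies levels 2..n (mu_2(0), sigma_2(0), mu_3(0), ...);
    level 1 carries no Gaussian belief of its own.  The returned
    trajectory stores level 1 in column 0 with the conventions
    mu_hat[:, 0] = predictive probability, pi_hat[:, 0] = its Bernoulli
    precision, mu[:, 0] = posterior state probability mu_1, delta[:, 0] =
    the VAPE delta_1, and pi[:, 0] = pi_hat_1 (no separate posterior
    precision exists at a binary level); v[:, 0] is NaN.
    """
    n = params.n_levels
    if init.n_levels != n - 1:
        raise ValueError(
            f"initial belief must cover levels 2..{n} ({n - 1} entries), "
            f"got {init.n_levels}")
    K = series.K
    traj = Trajectory(
        mu_hat=np.full((K, n), math.nan), pi_hat=np.full((K, n), math.nan),
        v=np.full((K, n), math.nan), mu=np.full((K, n), math.nan),
        pi=np.full((K, n), math.nan), delta=np.full((K, n), math.nan),
        delta_u=np.full(K, math.nan),
    )
    # beliefs over levels 2..n, array index j = level - 2
    mu = np.array(init.mu0, dtype=float)
    pi = 1.0 / np.array(init.sigma0, dtype=float)
    for k in range(K):
        t = series.t[k]
        u = series.u[k]
        mu_prev, pi_prev = mu.copy(), pi.copy()

        # predictions, levels 2..n (from previous posteriors)
        mu_hat = mu_prev.copy()
        v = np.empty(n - 1)
        for i in range(2, n):  # coupled levels
            v[i - 2] = _coupling_variance(t, params.kappa_at(i), mu_prev[i - 1],
                                          params.omega_at(i), trial=k + 1, level=i)
        v[n - 2] = t * params.theta
        pi_hat = 1.0 / (1.0 / pi_prev + v)

        mu_hat_1, pi_hat_1 = predict_first_level_binary(mu_prev[0])
        traj.mu_hat[k, 0] = mu_hat_1
        traj.pi_hat[k, 0] = pi_hat_1
        traj.mu_hat[k, 1:] = mu_hat
        traj.pi_hat[k, 1:] = pi_hat
        traj.v[k, 1:] = v

        if math.isnan(u):
            # missing input: prediction step only
            mu, pi = mu_hat, pi_hat.copy()
            traj.mu[k, 1:] = mu
            traj.pi[k, 1:] = pi
            traj.pi[k, 0] = pi_hat_1
            continue

        mu1 = infer_binary_state(mu_hat_1, u, input_model)
        delta_1 = mu1 - mu_hat_1
        pi2 = pi_hat[0] + 1.0 / pi_hat_1
        mu2 = mu_prev[0] + delta_1 / pi2
        mu[0], pi[0] = mu2, pi2

        # levels 3..n: generic VOPE updates; level below is i-1 (index i-3)
        for i in range(3, n + 1):
            j = i - 3
            delta_below = volatility_prediction_error(
                mu[j], 1.0 / pi[j], mu_hat[j], 1.0 / pi_prev[j], v[j],
                trial=k + 1, level=i - 1)
            mu[j + 1], pi[j + 1] = update_higher_level(
                mu_hat[j + 1], pi_hat[j + 1], delta_below, params.kappa_at(i - 1),
                v[j], pi_hat[j], pi_prev[j], trial=k + 1, level=i)
            traj.delta[k, i - 2] = delta_below

        traj.mu[k, 0] = mu1
        traj.pi[k, 0] = pi_hat_1
        traj.delta[k, 0] = delta_1
        traj.mu[k, 1:] = mu
        traj.pi[k, 1:] = pi
    traj.psi = binary_learning_rates(traj)
    return traj


def binary_learning_rates(trajectory: Trajectory) -> np.ndarray:
    """Precision weights for the binary hierarchy.

    psi_2 = 1/pi_2 (the weight on delta_1 in the mu_2 update) and
    psi_i = pi_hat_{i-1}/pi_i for i >= 3; level 1 has no learning rate
    of its own (NaN).
    """
    psi = np.full_like(trajectory.pi, math.nan)
    psi[:, 1] = 1.0 / trajectory.pi[:, 1]
    if trajectory.n_levels > 2:
        psi[:, 2:] = trajectory.pi_hat[:, 1:-1] / trajectory.pi[:, 2:]
    return psi


def simulate_binary_generative(params: BinaryHGFParams, input_model: BinaryInputModel,
                               init: InitialBelief, K: int, seed: int,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw binary states and inputs from the generative model.

    Levels 2..n evolve as Gaussian random walks starting from mu(0)
    (top-down within a step, as in the continuous model); then
    x_1^(k) ~ Bernoulli(s(x_2^(k))) and u is x_1 (noiseless) or
    N(eta_{x_1}, 1/pi_hat_u) (noisy).

    Returns (x1, x_upper, u) with x_upper of shape (K, n-1) holding
    levels 2..n.
    """
    n = params.n_levels
    if init.n_levels != n - 1:
        raise ValueError(f"initial belief must cover levels 2..{n}")
    rng = np.random.default_rng(seed)
    x = np.empty((K, n - 1))
    prev = np.array(init.mu0, dtype=float)
    for k in range(K):
        x[k, n - 2] = prev[n - 2] + math.sqrt(params.theta) * rng.standard_normal()
        for i in range(n - 1, 1, -1):  # levels n-1 .. 2
            var = _coupling_variance(1.0, params.kappa_at(i), x[k, i - 1],
                                     params.omega_at(i))
            x[k, i - 2] = prev[i - 2] + math.sqrt(var) * rng.standard_normal()
        prev = x[k]
    x1 = (rng.random(K) < sigmoid(x[:, 0])).astype(float)
    if input_model.mode == "noisy":
        means = np.where(x1 == 1.0, input_model.eta1, input_model.eta0)
        u = means + rng.standard_normal(K) / math.sqrt(input_model.pi_hat_u)
    else:
        u = x1.copy()
    return x1, x, u
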