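"""Decision models derived from loss functions.

A response model maps the agent's beliefs to the probability of an
observed binary choice y.  All models here derive from a quadratic loss
and use predictions available *before* the trial-k outcome: a choice at
trial k relies on beliefs carried over from trial k-1, i.e. on the
predictive probability mu_hat_1^(k) = s(mu_2^(k-1)) and, for the
dynamic-temperature variants, on mu_3^(k-1) or pi_hat_2^(k).

Families
--------
unit_square_sigmoid
    p(y=1) = m^zeta / (m^zeta + (1-m)^zeta) with m = mu_hat_1 and a
    constant inverse response noise zeta; the identity map at zeta = 1,
    a step function as zeta -> infinity.
volatility_temperature
    Same rule with zeta replaced per trial by the inverse volatility
    estimate exp(-mu_3): the more volatile the agent believes the world,
    the noisier its behavior.  No free parameter.
precision_temperature
    zeta replaced per trial by pi_hat_2, the precision of the level-2
    prediction (precision as inverse decision temperature).  No free
    parameter.
bandit_softmax
    Two options A/B with trial-wise rewards r_A/r_B; expected losses
    lbar(1) = -r_B mu_hat_1 and lbar(0) = -r_A (1 - mu_hat_1), choices
    Boltzmann-distributed: p(y=1) = s(zeta (r_B mu_hat_1 - r_A (1 -
    mu_hat_1))).  ``sign_flipped_softmax`` flips this sign to reproduce a variant
    in which the *less* rewarding option becomes more likely — kept only
    for comparison, since it contradicts the loss-minimizing derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hgfilter.binary import sigmoid
from hgfilter.continuous import Trajectory, TrialSeries

__all__ = [
    "ResponseParams",
    "ResponseModelSpec",
    "FAMILIES",
    "expected_loss_binary",
    "unit_square_sigmoid_likelihood",
    "dynamic_temperature_likelihood",
    "bandit_softmax_likelihood",
    "choice_probabilities",
    "simulate_responses",
    "log_likelihood_series",
]

# probabilities entering logs are clamped to [EPS, 1 - EPS]
EPS = 1e-15

FAMILIES = (
    "unit_square_sigmoid",
    "volatility_temperature",
    "precision_temperature",
    "bandit_softmax",
)


@dataclass(frozen=True)
class ResponseParams:
    """Response parameters zeta (inverse decision temperature / noise)."""

    zeta: float = 1.0

    def __post_init__(self):
        if not self.zeta > 0:
            raise ValueError("zeta must be positive")


@dataclass(frozen=True)
class ResponseModelSpec:
    """Choice of decision-model family plus its parameters.

    The dynamic-temperature families have no free zeta; specifying one
    for them is rejected.
    """

    family: str = "unit_square_sigmoid"
    params: ResponseParams | None = None
    sign_flipped_softmax: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown response-model family {self.family!r}")
        if self.family in ("volatility_temperature", "precision_temperature"):
            if self.params is not None:
                raise ValueError(f"{self.family} has no free response parameter")
        elif self.params is None:
            object.__setattr__(self, "params", ResponseParams())

    @property
    def has_zeta(self) -> bool:
        return self.family in ("unit_square_sigmoid", "bandit_softmax")

    def with_zeta(self, zeta: float) -> "ResponseModelSpec":
        if not self.has_zeta:
            raise ValueError(f"{self.family} has no zeta")
        return ResponseModelSpec(self.family, ResponseParams(zeta), self.sign_flipped_softmax)


def expected_loss_binary(mu_hat_1: float, y: int) -> float:
    """Expected quadratic loss E[(x_1 - y)^2] under belief mu_hat_1.

    Choosing y = 1 risks 1 - mu_hat_1; choosing y = 0 risks mu_hat_1.
    The loss-minimizing choice is y* = 1 iff mu_hat_1 > 1/2.
    """
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    return 1.0 - mu_hat_1 if y == 1 else float(mu_hat_1)


def _unit_square_log_p1(m, zeta):
    """log p(y=1) of the unit-square sigmoid, numerically stable."""
    m = np.clip(np.asarray(m, dtype=float), EPS, 1.0 - EPS)
    a = zeta * np.log(m)
    b = zeta * np.log1p(-m)
    norm = np.logaddexp(a, b)
    return a - norm, b - norm


def unit_square_sigmoid_likelihood(m, y, zeta: float):
    """p(y | m, zeta) = m^zeta / (m^zeta + (1-m)^zeta) for y = 1.

    Vectorized over m/y.  zeta = 1 reduces to p(y=1) = m; the rule tends
    to a step function around m = 1/2 as zeta grows.
    """
    lp1, lp0 = _unit_square_log_p1(m, zeta)
    y = np.asarray(y)
    return np.where(y == 1, np.exp(lp1), np.exp(lp0))


def dynamic_temperature_likelihood(mu_hat_1, temperature_source: str,
                                   trajectory_state, y):
    """Unit-square sigmoid with a per-trial inverse temperature.

    ``temperature_source`` is "exp_neg_mu3" (trajectory_state = the
    mu_3(k-1) prediction) or "pi_hat_2" (trajectory_state = pi_hat_2^(k)).
    """
    if temperature_source == "exp_neg_mu3":
        zeta_eff = np.exp(-np.asarray(trajectory_state, dtype=float))
    elif temperature_source == "pi_hat_2":
        zeta_eff = np.asarray(trajectory_state, dtype=float)
    else:
        raise ValueError(f"unknown temperature source {temperature_source!r}")
    lp1, lp0 = _unit_square_log_p1(mu_hat_1, zeta_eff)
    y = np.asarray(y)
    return np.where(y == 1, np.exp(lp1), np.exp(lp0))


def bandit_softmax_likelihood(mu_hat_1, r_a, r_b, zeta: float, y,
                              sign_flipped_softmax: bool = False):
    """Boltzmann choice over expected rewards in the two-option bandit.

    p(y=1) = s(zeta (r_B mu_hat_1 - r_A (1 - mu_hat_1))): the option with
    the larger expected reward is chosen with probability above one half.
    Adding a constant to both expected losses leaves the rule unchanged.
    """
    mu_hat_1 = np.asarray(mu_hat_1, dtype=float)
    drive = np.asarray(r_b) * mu_hat_1 - np.asarray(r_a) * (1.0 - mu_hat_1)
    if sign_flipped_softmax:
        drive = -drive
    p1 = sigmoid(zeta * drive)
    y = np.asarray(y)
    return np.where(y == 1, p1, 1.0 - p1)


def choice_probabilities(trajectory: Trajectory, spec: ResponseModelSpec,
                         series: TrialSeries | None = None) -> np.ndarray:
    """Per-trial p(y=1) implied by a belief trajectory.

    Uses the prediction columns of the trajectory (mu_hat_1, mu_hat_3,
    pi_hat_2), i.e. beliefs available before the trial's outcome.
    The bandit family needs the reward columns of ``series``.
    """
    m = trajectory.mu_hat[:, 0]
    if spec.family == "unit_square_sigmoid":
        lp1, _ = _unit_square_log_p1(m, spec.params.zeta)
        return np.exp(lp1)
    if spec.family == "volatility_temperature":
        if trajectory.n_levels < 3:
            raise ValueError("volatility_temperature needs a third level")
        zeta_eff = np.exp(-trajectory.mu_hat[:, 2])
        lp1, _ = _unit_square_log_p1(m, zeta_eff)
        return np.exp(lp1)
    if spec.family == "precision_temperature":
        zeta_eff = trajectory.pi_hat[:, 1]
        lp1, _ = _unit_square_log_p1(m, zeta_eff)
        return np.exp(lp1)
    # bandit_softmax
    if series is None or series.r_a is None or series.r_b is None:
        raise ValueError("bandit_softmax needs reward columns r_a/r_b")
    drive = series.r_b * m - series.r_a * (1.0 - m)
    if spec.sign_flipped_softmax:
        drive = -drive
    return sigmoid(spec.params.zeta * drive)


def simulate_responses(trajectory: Trajectory, spec: ResponseModelSpec, seed: int,
                       series: TrialSeries | None = None) -> np.ndarray:
    """Draw one binary response per trial from the response distribution."""
    p1 = choice_probabilities(trajectory, spec, series)
    rng = np.random.default_rng(seed)
    return (rng.random(p1.size) < p1).astype(float)


def log_likelihood_series(trajectory: Trajectory, y: np.ndarray,
                          spec: ResponseModelSpec,
                          series: TrialSeries | None = None) -> float:
    """Sum of log choice probabilities; missing (NaN) responses add zero."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != trajectory.K:
        raise ValueError("responses must align with the trajectory")
    p1 = np.clip(choice_probabilities(trajectory, spec, series), EPS, 1.0 - EPS)
    observed = ~np.isnan(y)
    yo = y[observed]
    po = p1[observed]
    return float(np.sum(yo * np.log(po) + (1.0 - yo) * np.log1p(-po)))
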