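"""Compiled scalar-loop filter for the three-level binary HGF.

Model inversion (MAP search, Metropolis-within-Gibbs sampling, recovery
grids) evaluates the filter ~10^5-10^6 times; this module provides a
single-function transcription of the noiseless three-level update loop
that numba can compile.  It mirrors the operation order of
:func:`hgfilter.binary.filter_sequence_binary` exactly, so the two paths
agree bitwise (asserted in the test suite).  Without numba the same
function runs as plain Python, just slower.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def filter_binary3(u, t, kappa, omega, theta, mu2_0, sigma2_0, mu3_0, sigma3_0):
    """Noiseless three-level binary HGF filter over K trials.

    Returns (ok, viol_trial, mu_hat_1, pi_hat_2, mu_hat_3, mu2, pi2,
    mu3, pi3) where ok is False when a precision was pushed non-positive
    or the volatility coupling overflowed; viol_trial is the 1-based
    trial of the violation.  mu_hat_3 is the trial-k prediction
    mu_3(k-1), used by dynamic-temperature decision models.
    """
    K = u.shape[0]
    mu_hat_1 = np.empty(K)
    pi_hat_2 = np.empty(K)
    mu_hat_3 = np.empty(K)
    mu2_out = np.empty(K)
    pi2_out = np.empty(K)
    mu3_out = np.empty(K)
    pi3_out = np.empty(K)

    if sigma2_0 <= 0.0 or sigma3_0 <= 0.0 or theta <= 0.0 or kappa <= 0.0:
        return False, 1, mu_hat_1, pi_hat_2, mu_hat_3, mu2_out, pi2_out, mu3_out, pi3_out

    mu2 = mu2_0
    pi2 = 1.0 / sigma2_0
    mu3 = mu3_0
    pi3 = 1.0 / sigma3_0

    for k in range(K):
        tk = t[k]
        arg = kappa * mu3 + omega
        if not math.isfinite(arg) or arg > 700.0:
            return False, k + 1, mu_hat_1, pi_hat_2, mu_hat_3, mu2_out, pi2_out, mu3_out, pi3_out
        v2 = tk * math.exp(arg)
        if v2 <= 0.0:  # exp underflow: no usable volatility information
            return False, k + 1, mu_hat_1, pi_hat_2, mu_hat_3, mu2_out, pi2_out, mu3_out, pi3_out
        v3 = tk * theta
        pihat2 = 1.0 / (1.0 / pi2 + v2)
        pihat3 = 1.0 / (1.0 / pi3 + v3)

        muhat1 = 0.5 * (1.0 + math.tanh(0.5 * mu2))
        if muhat1 < 1e-15:
            muhat1 = 1e-15
        elif muhat1 > 1.0 - 1e-15:
            muhat1 = 1.0 - 1e-15
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))

        mu_hat_1[k] = muhat1
        pi_hat_2[k] = pihat2
        mu_hat_3[k] = mu3

        delta1 = u[k] - muhat1
        pi2_new = pihat2 + 1.0 / pihat1
        mu2_new = mu2 + delta1 / pi2_new

        delta2 = (1.0 / pi2_new + (mu2_new - mu2) ** 2) / (1.0 / pi2 + v2) - 1.0
        w = kappa * v2 * pihat2
        pi3_new = pihat3 + 0.5 * w * w * (1.0 + (1.0 - 1.0 / (v2 * pi2)) * delta2)
        if not (pi3_new > 0.0) or not math.isfinite(pi3_new):
            return False, k + 1, mu_hat_1, pi_hat_2, mu_hat_3, mu2_out, pi2_out, mu3_out, pi3_out
        mu3_new = mu3 + 0.5 * kappa * v2 * pihat2 / pi3_new * delta2

        mu2 = mu2_new
        pi2 = pi2_new
        mu3 = mu3_new
        pi3 = pi3_new
        mu2_out[k] = mu2
        pi2_out[k] = pi2
        mu3_out[k] = mu3
        pi3_out[k] = pi3

    return True, 0, mu_hat_1, pi_hat_2, mu_hat_3, mu2_out, pi2_out, mu3_out, pi3_out


def warm_up() -> None:
    """Trigger JIT compilation once (a few seconds) so timings elsewhere are flat."""
    u = np.array([1.0, 0.0, 1.0])
    t = np.ones(3)
    filter_binary3(u, t, 1.0, -4.0, 0.0025, 0.0, 1.0, 1.0, 1.0)
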