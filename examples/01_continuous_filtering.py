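"""Filter a drifting quantity whose volatility itself drifts.

Simulates a two-level hierarchy of Gaussian random walks — the hidden
quantity x1 and its log-volatility x2 — plus noisy observations of x1,
then runs the filter on those observations.  The filter tracks both the
quantity and the volatility, adapting its learning rate trial by trial.
"""

import numpy as np

from hgfilter import (
    ContinuousInputModel,
    InitialBelief,
    PerceptualParams,
    TrialSeries,
    filter_sequence,
    simulate_generative,
)

params = PerceptualParams(kappa=(1.0,), omega=(-3.0,), theta=0.05)
input_model = ContinuousInputModel(pi_hat_u=10.0)   # observation noise var 0.1
init = InitialBelief(mu0=(0.0, 0.0), sigma0=(1.0, 1.0))

x, u = simulate_generative(params, input_model, init, K=500, seed=42)
traj = filter_sequence(TrialSeries(u=u), params, input_model, init)

rmse_filter = np.sqrt(np.mean((traj.mu[:, 0] - x[:, 0]) ** 2))
rmse_raw = np.sqrt(np.mean((u - x[:, 0]) ** 2))
corr_vol = np.corrcoef(traj.mu[:, 1], x[:, 1])[0, 1]

print(f"tracking RMSE of the filtered mean : {rmse_filter:.4f}")
print(f"tracking RMSE of the raw input     : {rmse_raw:.4f}")
print(f"correlation of mu_2 with true x_2  : {corr_vol:.3f}")
print(f"learning rate psi_1 range          : "
      f"[{traj.psi[:, 0].min():.4f}, {traj.psi[:, 0].max():.4f}]")

# The filtered mean beats the raw observations because the filter pools
# information over trials, weighting each prediction error by a dynamic
# learning rate; the positive correlation shows the volatility level
# tracks the true (unobserved) log-volatility.
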