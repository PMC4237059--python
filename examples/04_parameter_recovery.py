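"""Small parameter-recovery study with posterior calibration.

For each cell of a kappa x zeta grid, an agent with known parameters is
simulated on the shared 320-trial input sequence, its choices are drawn
from the unit-square sigmoid, and MAP estimation recovers the
parameters.  A posterior chain for one cell yields 95% posterior
central intervals (PCIs) for kappa.  Ten replicates per cell keep this
example quick; the test suite runs the fuller version.
"""

from hgfilter import RecoveryDesign, run_recovery_grid, summarize_recovery

design = RecoveryDesign(kappa_grid=(0.5, 3.5), zeta_grid=(0.5, 24.0),
                        reps=10, seed=3)
report = run_recovery_grid(design)
tables = summarize_recovery(report)

print(f"grid run: {len(report.estimates)} fits, {report.n_failures} failures, "
      f"{report.runtime_s:.1f} s")
print("\nRMSE of kappa estimates by decision noise (zeta):")
for _, row in tables["rmse_kappa_by_zeta"].iterrows():
    print(f"  zeta = {row['zeta_true']:>4}: RMSE = {row['rmse']:.3f}")
print("\nmedian kappa estimate per cell:")
for _, row in tables["median_kappa"].iterrows():
    print(f"  true kappa = {row['kappa_true']}, zeta = {row['zeta_true']:>4}: "
          f"median estimate = {row['median']:.3f}")

# PCI calibration for one cell (MCMC on top of each MAP fit)
mcmc_design = RecoveryDesign(kappa_grid=(1.5,), zeta_grid=(24.0,), reps=5,
                             seed=4, run_mcmc=True,
                             mcmc_chain_length=10_000, mcmc_burn_in=1_000)
coverage = summarize_recovery(run_recovery_grid(mcmc_design))["coverage"]
print(f"\n95% PCI coverage of kappa at zeta = 24 "
      f"({mcmc_design.reps} replicates): "
      f"{coverage['coverage'].iloc[0]:.2f}")
print("Estimates sharpen as decision noise falls (zeta = 24 vs 0.5), and")
print("the posterior intervals should contain the true kappa most of the time.")
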