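# Methods

## Generative model and filtering

The model is a hierarchy of n coupled Gaussian random walks.  Level i
evolves with step variance t·f_i(x_{i+1}), f_i(x) = exp(κ_i x + ω_i);
the top level uses a constant ϑ.  The factor t (inter-trial interval,
default 1) makes step variances proportional to elapsed time, the
defining property of a random walk, so irregularly sampled data need no
special handling.  Observations enter at the bottom: a Gaussian channel
u ~ N(x_1, 1/π̂_u) in the continuous model; in the binary model x_1 is
Bernoulli with p(x_1=1) = s(x_2) and u is either x_1 itself
("noiseless") or Gaussian around η_1/η_0 ("noisy").

Filtering assumes Gaussian posteriors N(μ_i, 1/π_i) per level and
applies the closed-form one-step updates quoted in the README.  The
update schedule within a trial is: all predictions from the previous
trial's posteriors; the level-1 update from the input; then levels 2..n
in ascending order, each consuming the volatility prediction error
(VOPE) of the just-updated level below.  The equations deliberately mix
time indices — the VOPE uses the *current* posterior of the level below
while the precision update's 1/(v·π_{i-1}) term uses the
*previous-trial* posterior precision — and they are transcribed exactly
as stated, without re-deriving the underlying variational argument.
The two time-indexings are not interchangeable; we treat the printed
form as authoritative and make no attempt to "repair" it.

Interpretation: σ_i is informational uncertainty (what the agent does
not know), v_i environmental uncertainty (what may have changed);
their ratio inside the updates produces trial-wise learning rates
ψ_i = π̂_{i-1}/π_i (ψ_2 = 1/π_2 in the binary model), exposed as
diagnostics.

## Numerical choices

* The level-1 continuous update *is* the exact conjugate Gaussian
  update; the test suite asserts this equivalence against the closed
  form on random instances, and the binary state inference is likewise
  checked against a directly coded Bayes rule over the two-component
  mixture.
* The logistic sigmoid is evaluated as 0.5(1+tanh(x/2)) and its output
  clipped to [1e-15, 1−1e-15] before forming the Bernoulli precision
  1/(μ̂₁(1−μ̂₁)), keeping it finite when μ₂ saturates the sigmoid in
  float64 (|μ₂| ≳ 37).  Probabilities entering logarithms anywhere in
  the likelihood pipeline are clipped at the same 1e-15.
* exp(κμ+ω) carries an overflow guard (argument > 700 → model-violation
  error naming trial and level).  A posterior precision pushed to zero
  or below — possible when ϑ is large — raises the same error class;
  during optimization and sampling the objective maps any such
  breakdown to a large negative sentinel (−1e12) so that search
  retreats instead of crashing.
* Missing inputs (NaN) trigger the prediction step only: beliefs
  diffuse, nothing is updated.  Missing responses contribute zero to
  the likelihood.
* The three-level noiseless binary filter — the case exercised ~10⁶
  times by the recovery grid and the sampler — has a scalar-loop
  transcription compiled with numba when available.  It mirrors the
  reference implementation's operation order exactly; a test asserts
  bitwise (not approximate) agreement, including agreement on the trial
  index of a breakdown.  Scalar sigmoids use math.tanh rather than
  numpy's vectorized tanh because the latter may differ by one ulp from
  the libm call the compiled path makes.

## Decision models

All four response families derive from quadratic loss.  For the binary
reward task, expected losses are 1−μ̂₁ (choose 1) and μ̂₁ (choose 0);
softening the argmin yields the unit-square sigmoid with inverse noise
ζ > 0.  Decisions at trial k use beliefs from trial k−1 only, i.e. the
prediction columns of the trajectory (μ̂₁, μ₃(k−1), π̂₂^(k)).  The
dynamic-temperature variants substitute exp(−μ₃) or π̂₂ for ζ per trial
and have no free response parameter.  For the two-option bandit with
rewards r_A, r_B, the Boltzmann rule gives p(y=1) =
s(ζ(r_B μ̂₁ − r_A(1−μ̂₁))): the option with the larger expected reward
is the likelier choice.  A written variant of this rule with the
opposite sign exists in the literature and contradicts its surrounding
derivation; `sign_flipped_softmax=True` reproduces it for comparison but the
default follows the loss-minimizing direction.

## Priors, transforms and inversion

Each parameter carries a Gaussian prior in an *estimation space*:
native for unbounded parameters (ω, μ_i(0)), log for positive ones
(σ_i(0), ζ), and a scaled logit logit_a(x) = ln(x/(a−x)) for doubly
bounded ones (κ with a = 6; ϑ with a small bound such as 0.005, since
large ϑ violates the filter's assumptions).  A prior variance of zero
fixes a parameter; fixed parameters are excluded from search and cannot
be overridden.  The ζ prior "(48, 1)" is interpreted as mean ln 48 and
variance 1 *in log space* — the stated intent is shrinkage on decision
noise, and a log-space mean of ln 48 places that shrinkage where the
written native value sits.  When the response model does not contain
μ₃ (constant-ζ sigmoid, bandit), level 3's origin and scale are not
identified from behavior; `check_identifiability` warns unless two of
{μ₃(0), κ, ω} are fixed.

MAP estimation runs a Nelder–Mead simplex on −Z in estimation space
from the prior means, plus (by default) three seeded restarts jittered
by half a prior standard deviation; single-start search is available
and is what the recovery harness uses, trading a small robustness
margin for speed.  The Laplace log evidence is

    F = Z(ξ*) + (d/2) ln 2π − ½ ln det H,

with H the negative Hessian of Z at the MAP from central finite
differences (step 1e-4 per dimension in estimation space).  A
non-positive-definite H is repaired by eigenvalue clipping with a
warning.  On an exactly Gaussian log-joint this F equals the analytic
integral (asserted to 1e-6); model comparison uses Bayes factors
exp(F_b − F_a).

The sampler is Metropolis-within-Gibbs: one Gaussian proposal per
coordinate per sweep, in estimation space.  Proposal scales start at
0.4 prior standard deviations and are re-tuned every 100 burn-in sweeps
(widened above 50% recent acceptance, narrowed below 20%), then frozen,
so the retained chain is a fixed-kernel Markov chain.  Acceptance rates
outside [0.1, 0.7] produce a tuning warning.  95% posterior central
intervals (PCIs) exclude 2.5% of mass on each side and are reported in
native space (the transforms are monotone, so quantiles map through).

## Synthetic data and the recovery study

No public trial sequence exists for the serial-learning task this
machinery is typically applied to, so the input generator produces a
declared stand-in: a piecewise-Bernoulli sequence with a stable phase
(two long blocks, p = 0.8 then 0.2, covering half the trials) followed
by a volatile phase of 20-trial alternating blocks.  This emulates the
low/high-volatility phase structure of such tasks.  Consequences: the
recovery study's claims are *trends* (error falls as decision noise
falls; estimates order correctly; intervals calibrate), not cell-exact
values, and passing tests say nothing about any particular empirical
sequence.

The recovery harness simulates, per (κ, ζ) cell, an agent filtering the
shared input sequence with ω = −4, ϑ = 0.0025, μ₂(0) = 0, σ₂(0) = 1,
μ₃(0) = 1, σ₃(0) = 1, draws unit-square-sigmoid choices, and refits six
free parameters under the standard prior set.  Desk-scale defaults are
a 2×2 grid (κ ∈ {0.5, 3.5} × ζ ∈ {0.5, 24}) with 50 replicates of 320
trials and, for calibration, 20 replicates with 20 000-sample chains
(2 000 burn-in) — sizes chosen so the whole study runs in minutes on
one core while the trend statistics remain stable across seeds; the
full-scale design (7×4 grid, 1 000 replicates, half-million-sample
chains) is expressible through `RecoveryDesign` but is not a default.
Summaries report RMSE of κ̂ per noise level, RMSE of ln ζ̂ (noise lives
on a log scale), medians per cell, and PCI coverage of κ.

The twin-agent sensory-uncertainty scenario runs 640 trials with
μ₂(0) = μ₃(0) = 0, σ₂(0) = σ₃(0) = 1, κ = 1, ω = −3, ϑ = 0.7, inputs
u ~ N(x₁, 0.1), and compares assumed input precisions 1000 vs 10 with
ζ = 8 choices on identical inputs.

## Known limitations

* The filter is a variational approximation; it can break down (and
  reports doing so) for large ϑ or extreme parameter settings, which is
  why ϑ and κ are bounded during estimation.
* Only d = 2 outcome categories are supported in the binary model.
* Gradient-based optimization and full variational inversion are out of
  scope; the Laplace evidence stands in for a variational free-energy
  bound, and the Gibbs sampler for full-posterior methods.
* Bandit fitting estimates ζ from choices given rewards; exploration is
  modelled only through ζ, not as a separate bonus.
* Generative simulation starts latent states exactly at μ(0) rather
  than drawing them from the initial belief; for the long sequences
  used here the difference is immaterial, but K = 1 simulations inherit
  it.
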