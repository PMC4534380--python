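# Methods

## Model components

### Attractor dynamics (`battm.attractor`)

The decision state `z ∈ R^N` (one component per alternative) follows a
Hopfield network

    dz/dt = k ( L σ(z) + b_lin (g·1 − z) ),   L = b_lat (I − J),

where `σ` is an elementwise logistic with slope `r_sig` and centre `o`,
and `J` is the all-ones matrix. Defaults: `k=4`, `g=10`, `r_sig=1`,
`o=g`, `b_lat=1.7`, `b_lin=b_lat/(2g)`, `N=2`. With `o=g` and
`b_lat/b_lin = 2g` the one-winner configurations are stable; for the
defaults the two stable fixed points sit at `[9.9991, 0.0045]` and its
mirror image, and the unstable equal-activity equilibrium is at
`c·1` with `c ≈ 7.872`.

Fixed points are located numerically (Powell-hybrid root refinement
seeded at `g·e_m`, drift residual < 1e−8, eigenvalue check of the
analytic Jacobian) rather than assumed to equal `g·e_m`: the confidence
criterion evaluates a density *at* the fixed point, so even sub-percent
location errors would bias confidence. The neutral state is found by
Brent root search of the scalar diagonal drift on `[0, g]`; it is
required to be unstable off the diagonal, and a stable diagonal
equilibrium (possible for weak lateral inhibition) is reported as an
error rather than silently returned.

The *pure attractor baseline* shares the same `HopfieldParams` and adds
evidence directly to the state: `z_t = z_{t−Δt} + Δt f(z) + I_t` with
`I_t = Δt·I + v_t`, `v_t ~ N(0, 0.2²)` on the currently true
alternative's component. Comparisons between the two architectures
therefore differ only in how evidence reaches the state.

### Stimulus model (`battm.stimulus`)

Observations are feature vectors `x_t ~ N(μ_i, s² I)` where `i` is the
scheduled alternative and `s` is the noise level; defaults
`μ₁ = [0.71, 0.71]`, `μ₂ = [−0.71, −0.71]` (opposite points near the
unit circle). Schedules are lists of `(alternative, duration_ms)`
segments, which expresses mid-trial category switches.

For all quantitative experiments a fresh draw is made every model step
(`frame_ms = dt_ms = 4`). Holding draws for 40 ms display frames is
supported (it reproduces the illustrative single-dot stimulus plots) but
is not the quantitative convention: holding frames correlates
consecutive observations, reduces the evidence per unit time, and —
checked during calibration — flattens the dependence of re-decision
performance on the dynamics uncertainty that the model is meant to
expose.

### Generative model and filter (`battm.ukf`)

State equation: one Euler step of the Hopfield drift plus Gaussian state
noise with per-step covariance `q² Δt_model I` (the Euler–Maruyama
composition of the continuous-time noise intensity `q²/Δt` with the `Δt`
step factor). Observation equation: `x = M σ_out(z) + v`,
`v ~ N(0, r² I)`, with the interpolation sigmoid `σ_out` (slope 0.7,
centre `g/2`) chosen shallower than the dynamics sigmoid so the map is
near-linear over the transit between fixed points. Note that with the
default symmetric prototypes `M` is rank one: only the contrast between
alternatives is observable, the summed activity is constrained by the
dynamics alone.

Inference uses a non-augmented unscented Kalman filter with additive
noise handling: the scaled unscented transform (α=0.01, β=2, κ=3−D,
D = N = 2) propagates the belief through the transition and observation
maps; `Q` and `R` are added to the transformed covariances. The gain is
`K = Ĉ Σ̂⁻¹` with `Ĉ` the state-observation cross-covariance of the
sigma points. After every update the posterior covariance is
re-symmetrised; Cholesky factorisations retry with `1e−10·I` jitter
(three escalating attempts) before raising. All filter code is
batch-first (`(B, N)` means, `(B, N, N)` covariances), so a thousand
trials advance in lockstep through vectorised steps; single trials are
the `B=1` case, and a dedicated test pins batch/single equality.

### Temporal calibration

The dynamics is dimensionless; the package anchors it to wall-clock time
through a single parameter, `time_unit_ms = 50`: one filter step of
`dt_ms = 4` advances the dynamics by `Δt_model = 0.08` time units (the
rate constant `k` is per time unit). This value was fixed once, by
requiring the default-parameter model to reproduce the reference
behavioural signatures jointly — re-decision time-in-correct-state
percentages around 73/53/35% for q = 1.0/0.5/0.1 at s=4, r=2.4;
initial decisions of roughly 100 ms of accumulation at matched
uncertainties; overshoot trajectories past the fixed point when r is
far below s; and sub-second, super-100-ms reaction-time scales across
the speed-accuracy map. Readings of the step as 4 ms of "seconds-based"
dynamics (Δt_model = 0.004) or as one full time unit (Δt_model = 1)
fail these jointly: the former gives second-scale, low-confidence
decisions, the latter makes the attractor contraction so strong per
step that moderate dynamics uncertainty can never drive a re-decision.

### Decision criterion and trials (`battm.decision`)

Confidence in alternative `i` at time `t` is the posterior density
`N(φ_i; z̄_t, P̄_t)` — a density, which may exceed 1 and is never
normalised into a probability. A decision falls at the first step where
any alternative's confidence reaches `λ = 0.02`; ties go to the larger
density, exact ties to the lower index (deterministic by construction).
Filtering always continues to the end of the stimulus, so post-decision
confidence (read out 100 ms after the crossing, i.e. during the motor
half of the non-decision time) and re-decision measures come from the
same run.

The non-decision time `T0 = 200 ms` is honoured in two modes:

* `dead_time` — accumulation starts after `T0` of stimulus time; the
  reaction time is the crossing time and contains `T0`. Used for
  single-decision experiments (speed-accuracy maps, fitting, confidence
  by coherence).
* `onset` — accumulation starts at stimulus onset and `T0` is added to
  the crossing time as motor latency. Used for re-decision and gain
  analyses, where the criterion is evaluated over the whole trial; the
  example switch-trial traces (initial decisions well before 200 ms of
  stimulus time) show this is the convention those analyses require.

The re-decision metric is the fraction of *all* trial steps at which the
currently generating alternative's confidence meets the bound; its
denominator is the full trial, so even perfect tracking scores below
100% by the time spent deciding and re-deciding. Trials without a
crossing by `timeout_ms = 1000` are flagged as timeouts; accuracy is
correct/decided with timeouts tracked separately, and map cells with
more than 50% timeouts are masked but never dropped.

### Experiments (`battm.experiments`)

Grid runners (speed-accuracy over `s × r`, re-decisions over `r × q`)
are log-grid friendly, compute per-cell metrics from a configurable
trial count, and derive one child seed per cell from the master seed, so
whole maps are bit-reproducible. Mean reaction times are reported for
correct trials (speed-accuracy map) or all responses (fitting), matching
the two summary conventions. The architecture contrast reports, for the
pure model, the winning component's state just before the stimulus
switch (which grows with the input level), and for the Bayesian model
the settled posterior mean over the last 200 ms before the switch
(which is invariant across uncertainty settings to well under 2%); the
settled value is used rather than the trajectory maximum because
transient overshoots vary by a few percent without bearing on fixed
point locations.

### Fitting (`battm.fitting`)

Per condition, the discrepancy between observed and simulated
(accuracy, mean RT) is

    D(s, r) = (A − Â)²/σ_A² + (RT − R̂T)²/σ_RT² + P(s, r),

with ad-hoc scales σ_A = 0.05 and σ_RT = 10 ms, `Â`, `R̂T` estimated
from simulated trials (1000 by default). The penalty `P` exceeds 10,000
when more than half of the simulated trials time out, or when `r` lies
below the straight line through (s=1.45, r=0.47) and (s=80, r=3.66) in
log-log coordinates — the overshoot regime where too little sensory
uncertainty destabilises trajectories. The boundary is implemented in
the (s, r) plane (r below the line), the orientation under which the
model's own admissible reference settings and every row of the packaged
coherence table fall outside the penalty region; the penalty is graded
beyond the floor to give the sampler a slope.

`mcmc_fit` embeds `exp(−D/2)` in an adaptive Metropolis sampler with one
delayed-rejection stage (DRAM) over `(log s, log r)`: initial diagonal
proposal SD 0.3, covariance re-estimated from the chain every 100 steps
(scaled by 2.38²/d plus 1e−6 I), delayed-rejection proposal at 0.2×
scale with the standard two-stage acceptance ratio, wide `N(0, 10²)`
priors in log space, and the hard constraint `s > 0.1`. The objective is
stochastic; every proposal gets a fresh child seed (noisy Metropolis,
with the current state's value cached). The default retention rule —
3000 iterations, drop the first 499, keep every 5th — retains exactly
501 samples; the reported point estimate is the retained sample with the
smallest discrepancy. Accuracy and mean RT identify (s, r) only up to a
soft trade-off ridge at mid difficulties, so the sampler is validated by
parameter recovery on synthetic summaries (within 25%), not by exact
posterior shape.

`fit_kprime` estimates the scaling constant of `r² = K′/c` (coherence
`c` in percent) by the closed form `Σ(r²/c) / Σ(1/c²)` over all `c > 0`
rows of the packaged per-coherence table (an option restricts to
`c ≤ 25.6`, where the law holds best); the closed form is cross-checked
against a grid-search oracle in the tests.

## What the synthetic stimuli do and do not emulate

The generator produces exactly the abstraction the model assumes:
isotropic Gaussian feature vectors around per-alternative prototypes,
with scheduled category switches. It does not render random-dot
kinematograms, model feature extraction from raw stimuli, temporal
autocorrelation of real sensory evidence, lapses, or urgency. Passing
tests therefore certify the inference and decision machinery under the
model's own input assumptions — not that those assumptions describe any
particular experiment's stimulus pathway.

## Problem sizes used in the shipped runs

Acceptance benchmarks use the study-scale 1000 trials per setting.
Qualitative pattern tests run at reduced counts chosen for desk-scale
runs (40–250 trials per cell, short DRAM chains of a few hundred
iterations with 150–200 simulated trials per proposal); each test states
its count. The batched filter advances ~1000 trials of 400 steps in a
couple of seconds on one core.

## Known limitations

* Two alternatives are the tested path; the code is written for general
  `N` but all calibrated results are binary.
* The temporal calibration (`time_unit_ms = 50`) is a package-level
  choice pinned to the reference behavioural signatures; other values
  rescale reaction times and shift the useful ranges of `q` and `r`.
* No urgency signal, no within-trial adaptation of `r`, no extended
  Kalman or particle-filter back-ends, no learning of the prototype
  matrix `M`.
* Confidence is reported as a posterior density; mapping it onto
  percent-scale confidence ratings would require an additional link
  function that is out of scope.
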