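# battm — a Bayesian attractor model of perceptual decision making

`battm` simulates and fits a model of how a decision maker turns a stream
of noisy sensory features into categorical choices, re-decisions after a
stimulus change, top-down gain modulation, and an explicit, ongoing
measure of decision confidence. It is aimed at computational
neuroscientists and psychophysicists who want a quantitative model of
choice, reaction time and confidence that goes beyond bounded-accumulation
(drift-diffusion) and plain winner-take-all attractor accounts.

## The model

**Decision state.** A Hopfield network with one unit per choice
alternative provides winner-take-all dynamics

```
dz/dt = k ( L σ(z) + b_lin (g·1 − z) ),    L = b_lat (I − J),
```

with logistic σ, all-ones matrix J, and defaults k=4, g=10, b_lat=1.7,
b_lin=b_lat/2g. Under the stability condition (sigmoid centred at g,
b_lat/b_lin = 2g) the dynamics has one stable fixed point φ_i per
alternative (one unit at ≈g, the rest at ≈0) and an unstable
equal-activity equilibrium μ₀ used as the trial's starting belief.

**Generative model.** Rather than injecting evidence into z directly, the
dynamics is used as the state equation of a generative model: the decision
maker believes z evolves by one Euler step plus state noise of magnitude
q ("dynamics uncertainty"), and that observed feature vectors are an
interpolation of the alternatives' prototype vectors,
`x = M σ_out(z) + v`, with observation noise of expected SD r ("sensory
uncertainty"). True stimuli are drawn as `x ~ N(μ_i, s² I)` with noise
level s; defaults μ₁ = [0.71, 0.71], μ₂ = [−0.71, −0.71].

**Inference and decision.** The generative model is inverted online with
an unscented Kalman filter (scaled unscented transform, α=0.01, β=2,
κ=3−D), giving a Gaussian posterior N(z̄ₜ, P̄ₜ) over the decision state.
The *confidence* in alternative i is the posterior density evaluated at
φ_i — a density, not a probability — and a decision is made the first
time any confidence reaches the bound λ=0.02. The Kalman gain
K = Ĉ Σ̂⁻¹ couples the decision state back to evidence extraction: the
state-observation cross-covariance Ĉ is large between fixed points and
small at them, producing within-trial, state-dependent gain modulation.

Because q and r are uncertainties of the *decision maker* while s belongs
to the *stimulus*, the model separates speed-accuracy (s vs r), the
stability-flexibility of re-decisions (q), and confidence levels (both)
with interpretable parameters, and fits behavioural summaries per
condition.

## Worked example

`examples/03_redecisions.py` runs 500 switching trials (800 ms per
alternative, s=4, r=2.4) per dynamics-uncertainty setting:

```
q = 1.0:  70.2% of trial time in the correct decision state
q = 0.5:  53.2% of trial time in the correct decision state
q = 0.1:  39.1% of trial time in the correct decision state
```

The number is the mean percentage of trial time during which the
confidence criterion holds for the currently correct alternative. With
flexible dynamics (q=1.0) the model re-decides within a few hundred
milliseconds of the switch; with q=0.1 it clings to its first decision
and only the pre-switch half of the trial is ever credited.

The other scripts in `examples/` each demonstrate one capability:
single-trial traces, the speed-accuracy map, gain/cross-covariance
dynamics, post-decision confidence versus coherence, and DRAM fitting of
(s, r) to a behavioural summary together with the K′ scaling law
r² = K′/coherence.

A thin CLI mirrors the runners, e.g.

```
battm simulate --trials 100 --seed 1 --out trials.csv
battm kprime
```

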