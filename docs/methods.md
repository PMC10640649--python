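# Methods

## Problem and model

Intracellular organelles such as peroxisomes alternate between two
migration modes: slow, quasi-random motion while tethered to other
structures, and fast, persistent runs while bound to microtubules and
pulled by motor proteins. The directed episodes are rare and short, so
whole-track statistics (mean speed, MSD exponents) wash them out.
`pextrack` segments each 2-D track step-by-step with a two-state hidden
Markov model and then summarizes mode occupancy and switching rates per
cell and per experimental condition.

### Observables

From positions x_t (μm) sampled at interval Δt, each displacement step
yields

- a dimensionless instantaneous speed ι_t = |x_{t+1} − x_t| / Δt,
  expressed in units of 1 μm/s so that ln ι is well defined, and
- a signed relative turning angle α_t ∈ (−180°, 180°] between
  consecutive displacement vectors.

The observation for step t pairs that step's speed with the angle at
the vertex it shares with step t−1; the first step of a track carries
no angle and its emission uses the speed factor alone. Angle and speed
are treated as conditionally independent given the hidden state, so
the joint emission density factorizes.

Steps across gap-closed frame jumps use the true elapsed time
(frame difference × Δt); the angles touching a gap are marked absent
by default because the intermediate geometry is unknown. Zero-length
displacements are floored at ι = 10⁻⁹ inside the emission model to
keep the log-normal density finite, and the adjacent angles are marked
absent. Absent angles contribute a likelihood factor of 1 in both
states, which is unbiased because the factor is state-independent.

### Emission model

- Speed, both states: log-normal with state-specific location μ_ι,i
  and scale σ_ι,i (the mean and sd of ln ι). A log-normal respects
  positivity and keeps the EM M-step in closed form.
- Angle, random state s1: uniform over the circle (1/360 per degree).
- Angle, directed state s2: zero-mean normal with standard deviation
  σ_α,2 (degrees), truncated to (−180°, 180°] and renormalized. At
  the typical σ_α,2 ≈ 26° the truncation correction is below 1e−10;
  the truncated (rather than wrapped) form was chosen as the simplest
  density on the bounded support.

Working in degrees rather than radians only rescales both angle
densities by the same constant and therefore cannot change posteriors,
fits or decodings; degrees are used because spread parameters are
conventionally quoted that way.

### Occupancy vector π

π_i is interpreted as the overall proportion of steps a track spends
in state i. It serves as the prior in the single-observation Bayes
posterior and as the initial distribution when decoding. During EM
fitting the initial distribution is held fixed (one step contributes
negligibly to the likelihood of a long sequence) and π is estimated as
the time-averaged posterior occupancy Σ_t γ_t(i)/T at convergence.
This keeps EM monotone to machine precision — the textbook
initial-step update γ_0, which is degenerate for single sequences, is
available via `pi_update="initial"`.

## Fitting and decoding

Scaled Baum–Welch: forward variables are renormalized at every step,
so underflow cannot occur and the log-likelihood is the sum of log
scale factors. M-steps are the standard responsibility-weighted
closed forms; σ_ι,i uses the freshly updated μ_ι,i (the exact joint
maximizer), and σ_α,2 is estimated over steps with defined angles
only, using the untruncated normal form (exact up to the negligible
truncation correction). Parameter groups (`mu_iota`, `sigma_iota`,
`sigma_alpha2`, `pi`, `T`) can be frozen individually.

Numerical choices:

- convergence: |Δ log L| < 1e−6, at most 500 iterations;
- floors: σ_ι ≥ 1e−3, σ_α,2 ≥ 0.5°, applied only if a state's
  responsibility mass collapses (a warning is emitted);
- initialization (nothing frozen): μ_ι at the 25th/75th percentiles of
  ln ι, σ_ι at the overall spread of ln ι, σ_α,2 = 30°,
  π = [0.5, 0.5], T = [[0.9, 0.1], [0.1, 0.9]]. Deterministic, so
  repeated fits are bit-identical;
- label switching: after any fit with free μ_ι, states are reordered
  so μ_ι,1 < μ_ι,2 (s2 is the faster, directed state);
- Viterbi runs in log space; ties break toward s1.

Two-stage protocol for experimental data: stage 1 fits all parameters
on a designated set of mixed-mode tracks (per-track fits averaged by
default; a joint fit over concatenated sequences is available) to pin
down the emission densities; stage 2 freezes the emissions and fits
only {π, T} per track before decoding. Freezing matters: an
unconstrained two-state fit on a single-mode track will happily split
the one mode into slow/fast regimes, because even pure
Ornstein–Uhlenbeck speeds are autocorrelated.

## Synthetic track generator

The simulator is the validation substrate: a two-state Markov chain
(initial distribution pi0, per-step switch probabilities T12, T21)
selects the generative mode of each step.

Random mode — discrete Ornstein–Uhlenbeck velocity process:

    v_{t+1} = (1 − Δt/τ) v_t + √Δt · (√(2D)/τ) · ε_t,
    x_{t+1} = x_t + Δt v_{t+1},

with ε_t a pair of independent standard normals. Directed mode — the
previous heading is kept, the speed redrawn:

    ‖v‖_{t+1} ~ normal(v_mean, v_sd)   (negative draws rejected),
    v_{t+1} = v_t/‖v_t‖ · ‖v‖_{t+1} + ε_t,
    x_{t+1} = x_t + Δt v_{t+1}.

Defaults (the study conditions used throughout the tests and the
acceptance script): 100 tracks × 200 steps, Δt = 1 s, τ = 1.5 s,
D = 5 μm²/s, directed speed normal(10, 1) μm/s, unit directed-mode
velocity noise, T12 = T21 = 0.1, pi0 = [0.5, 0.5]. The initial
velocity is drawn from the discrete-OU stationary distribution; on
entering the directed mode at exactly zero velocity the heading is
drawn uniformly. Each track consumes its own substream spawned from
the root seed, so datasets replay exactly.

Two consequences of this discretization are worth keeping in mind when
interpreting validation numbers. First, the stationary per-component
velocity variance of the random mode is c²/(1 − a²) with
a = 1 − Δt/τ and c = √Δt·√(2D)/τ, which equals exactly 5 μm²/s² at
the defaults; the expected log speed of the random mode is then
E[ln‖v‖] = ln√5 + (ln 2 − γ)/2 ≈ 0.86, and fitted values of μ_ι,1
land near 0.91 (slightly above the stationary value because the
velocity relaxes over a few steps after each directed episode).
Second, with speeds near 10 μm/s in the directed mode the two speed
distributions barely overlap, so decoding accuracy on this generator
is high (≈ 99.5% of steps): most residual errors sit at mode
switches, where the OU velocity has not yet relaxed.

What the generator does not emulate: localization noise, confinement,
photo-physics, variable frame intervals, and the heavy-tailed
population heterogeneity of real cells. Passing validation here shows
the estimator recovers the generative process it models, not that real
tracks obey that process.

## MSD analysis

Per cell, the ensemble (from-origin) MSD

    MSD(t) = (1/N) Σ_i (x_{i,t} − x_{i,0})²

is computed over tracks with at least 50 steps (5 s at 10 frames/s),
each track contributing to the lags it reaches (per-lag N is
recorded). The anomaly exponent α is the OLS slope of log MSD against
log t, by default over 0.1–20 s (lag 0 cannot enter a log fit);
α < 1 subdiffusion, α = 1 Brownian, α > 1 superdiffusion. The fit is
unweighted; a time-averaged MSD variant is available behind a flag.
In the memoryless limit τ = Δt the simulator's random mode is an iid-
velocity random walk and the fitted α falls in [0.9, 1.1], which the
tests assert.

## Validation metrics and statistics

The directed state s2 is the positive class. Recall = TP/(TP+FN),
precision = TP/(TP+FP); F1 is the conventional 2PR/(P+R), and the
variant PR/(P+R) (half the conventional value) is reported alongside
as `f1_as_printed` for comparability with analyses using that form.
Zero-denominator ratios are reported as 0 with an `undefined` flag.

Sensitivity of the decoding to emission mis-specification is probed by
adding normal(0, σ) noise independently to both entries of each
track's fitted μ_ι and re-decoding; the pooled F1 (averaged over
repetitions) is reported per σ. At σ = 0 the curve equals the
unperturbed F1 exactly.

Directed-run statistics: for k = 1..k_max, the fraction of tracks
containing at least k consecutive s2 steps, with 95% percentile
bootstrap bands from resampling tracks with replacement (1000
resamples by default; the resampling unit is the track within a
condition).

Condition comparisons use a two-sided two-sample t-test on per-cell
values (Welch's form by default — robust to unequal variances; the
pooled-variance Student form is a flag) with Bonferroni correction
q = min(1, m·p) over the m pairwise comparisons performed in a run.

## Problem sizes

The default validation run (100 tracks × 200 steps, full per-track
EM fits, Viterbi decoding, 20-repetition perturbation curve) completes
in well under a minute on one CPU core; the test suite exercises the
same run once and reuses it across checks.

## Known limitations

- Exactly two states; no confined or anomalous-diffusion modes.
- 2-D tracks only.
- The turning-angle model ignores the mild forward bias that a
  persistent (OU) random mode produces; this slightly favors s2 for
  straight slow segments but is dominated by the speed factor in
  practice.
- Per-track stage-2 fits need enough steps to inform T; tracks are
  filtered to ≥ 50 steps by default.
- Downsampling a gapped track operates on position indices, not
  wall-clock times.
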