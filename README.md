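# pextrack

Two-state hidden Markov model segmentation of 2-D single-particle
tracks into **random** and **microtubule-directed** migration.

Organelles such as peroxisomes mostly jiggle in place — tethered,
quasi-random motion — but occasionally bind the microtubule network
and make fast, straight runs driven by motor proteins. These directed
episodes are rare and last only a few frames, so classic track
statistics (mean speed thresholds, MSD exponents) cannot resolve them
or the switching between modes. `pextrack` is for microscopists and
image analysts who have particle tracks (e.g. TrackMate exports) and
want per-step mode labels, per-track occupancy and switching rates,
and statistically sound comparisons between experimental conditions.

## Model

Each displacement step of a track yields two observables: the
dimensionless instantaneous speed ι_t = ‖x_{t+1} − x_t‖ / Δt (in
units of 1 μm/s) and the signed relative turning angle
α_t ∈ (−180°, 180°]. A hidden state s_t ∈ {s1 (random), s2
(directed)} evolves as a Markov chain with transition matrix T, and
emissions factorize given the state:

    p(o_t | s_i) = p(ι_t | s_i) · p(α_t | s_i)
    p(ι_t | s_i) = lognorm(μ_ι,i, σ_ι,i)
    p(α_t | s1) = uniform over the circle
    p(α_t | s2) = normal(0, σ_α,2), truncated to (−180°, 180°]

The occupancy vector π — the fraction of steps spent in each state —
acts as the state prior. Parameters are fitted with the scaled
Baum–Welch (EM) algorithm, optionally with parameter groups frozen
(the two-stage protocol fits emissions once on mixed-mode tracks, then
refits only {π, T} per track); the most probable state path comes from
the Viterbi algorithm. Fitted log-normal parameters convert to mean
speeds via ῑ = exp(μ + σ²/2) μm/s.

A built-in simulator generates switching-mode tracks with ground-truth
labels (random mode: discrete Ornstein–Uhlenbeck velocity process;
directed mode: persistent heading with redrawn speed), which is how
the whole chain — observables, EM, decoding, metrics — is validated.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from pextrack import SimParams, simulate_dataset, TwoStateHMM, expected_speed

ts, truth = simulate_dataset(SimParams(n_tracks=100, n_steps=200, seed=1))

model = TwoStateHMM().fit(ts.tracks[0])        # full fit on one track
print(np.round(model.params_.mu_iota, 2))      # [0.8  2.34]
print(np.round(model.params_.pi, 2))           # [0.61 0.39]
print(np.round(model.params_.T, 3))            # [[0.936 0.064]
                                               #  [0.102 0.898]]
states = model.predict(ts.tracks[0])           # 0 = random, 1 = directed
print(np.mean(states == truth["sim000"]))      # 1.0
```

The fitted speed locations say ln-speed centres of 0.8 (random) and
2.34 (directed); through ῑ = exp(μ + σ²/2) these are mean speeds of
about 2.8 and 10.4 μm/s for this simulated track — the directed mode
is the fast one, and for this track every step is labelled correctly.
π says the track spends ~61% of its steps in the random mode, and T
says the directed mode persists with probability ~0.9 per step.

The same workflow from the shell, over all 100 tracks:

```
$ pextrack validate --seed 1 --out results/validation
mean per-track accuracy: 99.5%
precision 0.993  recall 0.997  F1 0.995
mean fitted mu_iota: [0.91, 2.3]
```

meaning that with all parameters fitted per track, Viterbi decoding
recovers 99.5% of the generative states, and the across-track average
fitted log-speed centres are 0.91 / 2.30 for the two modes.

Other subcommands: `simulate` (tracks + ground truth to CSV),
`fit-emissions` / `scan` (the two-stage protocol for real TrackMate
CSV/XML data), `msd` (per-cell MSD curves and anomaly exponents),
`runs` (directed-run ratio curves with bootstrap CIs), `compare`
(per-cell condition comparisons, Welch t-test + Bonferroni).

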