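"""Synthetic switching-mode track generator with ground-truth states.

Tracks alternate between two generative modes driven by a two-state
Markov chain.  The random mode follows a discrete Ornstein-Uhlenbeck
velocity process,

    v_{t+1} = (1 - Δt/τ) v_t + √Δt (√(2D)/τ) ε_t,
    x_{t+1} = x_t + Δt v_{t+1},

with per-component standard-normal noise ε_t, velocity persistence τ
and diffusion coefficient D.  The directed mode keeps the previous
heading, draws a new speed from normal(v_mean, v_sd) and adds
per-component standard-normal velocity noise before stepping:

    ||v||_{t+1} ~ normal(v_mean, v_sd),
    v_{t+1} = v_t/||v_t|| · ||v||_{t+1} + ε_t,
    x_{t+1} = x_t + Δt v_{t+1}.

Defaults reproduce the validation conditions used throughout this
package: 100 tracks of 200 steps at Δt = 1 s, τ = 1.5 s, D = 5 μm²/s,
directed speed normal(10, 1) μm/s, symmetric per-step switching
probabilities of 0.1 and equal initial state probabilities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .tracks import Track, TrackSet

__all__ = ["SimParams", "LabeledTrack", "simulate_track", "simulate_dataset"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings.  Lengths in μm, times in seconds."""

    n_tracks: int = 100
    n_steps: int = 200
    dt: float = 1.0
    tau: float = 1.5          # OU velocity persistence
    D: float = 5.0            # diffusion coefficient, μm²/s
    v_dir_mean: float = 10.0  # directed-mode mean speed, μm/s
    v_dir_sd: float = 1.0
    dir_noise_sd: float = 1.0  # per-component velocity noise in directed mode
    T12: float = 0.1          # per-step switch probability random -> directed
    T21: float = 0.1
    pi0: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 0 or self.n_steps < 1:
            raise ValueError("need n_tracks >= 0 and n_steps >= 1")
        for name in ("dt", "tau", "D", "v_dir_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.v_dir_sd < 0 or self.dir_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for p in (self.T12, self.T21, *self.pi0):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.pi0[0] + self.pi0[1] - 1.0) > 1e-9:
            raise ValueError("pi0 must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi0"] = list(self.pi0)
        return d


@dataclass(frozen=True)
class LabeledTrack:
    """A simulated track together with its generative mode per step."""

    track: Track
    truth: np.ndarray  # (n_steps,) ints, 0 = random, 1 = directed

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=np.intp)
        if len(truth) != self.track.n_steps:
            raise ValueError("truth length must equal the number of steps")
        object.__setattr__(self, "truth", truth)


def _ou_stationary_sd(p: SimParams) -> float:
    """Per-component stationary sd of the discrete OU velocity."""
    a = 1.0 - p.dt / p.tau
    c = np.sqrt(p.dt) * np.sqrt(2.0 * p.D) / p.tau
    if abs(a) >= 1.0:
        raise ValueError("discrete OU update is unstable: need dt < 2*tau")
    return float(c / np.sqrt(1.0 - a * a))


def simulate_track(
    p: SimParams,
    rng: np.random.Generator,
    track_id: str = "sim0",
    cell_id: str = "simcell",
    condition: str = "sim",
) -> LabeledTrack:
    """Simulate one switching-mode track.

    The mode of each displacement step is drawn first (initial mode
    from ``pi0``, then per-step switches with probabilities T12/T21);
    positions are then generated mode-by-mode.  The initial velocity is
    drawn from the discrete-OU stationary distribution so the random
    mode starts in steady state; if the directed mode is entered at
    exactly zero velocity, the heading is drawn uniformly on the
    circle.
    """
    n = p.n_steps
    states = np.empty(n, dtype=np.intp)
    s = int(rng.random() >= p.pi0[0])
    switch = (p.T12, p.T21)
    for t in range(n):
        states[t] = s
        if rng.random() < switch[s]:
            s = 1 - s

    a = 1.0 - p.dt / p.tau
    c = np.sqrt(p.dt) * np.sqrt(2.0 * p.D) / p.tau
    v = rng.normal(0.0, _ou_stationary_sd(p), size=2)

    x = np.zeros((n + 1, 2))
    for t in range(n):
        if states[t] == 0:
            v = a * v + c * rng.normal(size=2)
        else:
            speed = rng.normal(p.v_dir_mean, p.v_dir_sd)
            while speed <= 0.0:  # physically a speed; redraw the rare negative
                speed = rng.normal(p.v_dir_mean, p.v_dir_sd)
            norm = np.hypot(v[0], v[1])
            if norm > 0.0:
                heading = v / norm
            else:
                phi = rng.uniform(0.0, 2.0 * np.pi)
                heading = np.array([np.cos(phi), np.sin(phi)])
            v = heading * speed + p.dir_noise_sd * rng.normal(size=2)
        x[t + 1] = x[t] + p.dt * v

    track = Track(
        track_id=track_id,
        frames=np.arange(n + 1, dtype=np.int64),
        positions=x,
        dt=p.dt,
        cell_id=cell_id,
        condition=condition,
    )
    return LabeledTrack(track=track, truth=states)


def simulate_dataset(
    p: SimParams, cell_id: str = "simcell", condition: str = "sim"
) -> tuple[TrackSet, dict[str, np.ndarray]]:
    """Simulate ``p.n_tracks`` independent tracks as one synthetic cell.

    Each track consumes its own substream spawned from ``p.seed``, so
    the dataset is reproducible as a whole and per track.

    Returns
    -------
    (TrackSet, dict)
        The tracks, and a mapping track_id -> ground-truth state array.
    """
    children = np.random.SeedSequence(p.seed).spawn(p.n_tracks)
    tracks, truth = [], {}
    width = max(3, len(str(max(p.n_tracks - 1, 0))))
    for i, ss in enumerate(children):
        tid = f"sim{i:0{width}d}"
        lt = simulate_track(
            p, np.random.default_rng(ss), track_id=tid, cell_id=cell_id, condition=condition
        )
        tracks.append(lt.track)
        truth[tid] = lt.truth
    return TrackSet(tracks), truth
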