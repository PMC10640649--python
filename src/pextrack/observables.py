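"""Conversion of track coordinates to HMM observables.

Each displacement step of a track yields a dimensionless instantaneous
speed ι_t (speed in μm/s divided by the reference speed 1 μm/s, so that
its logarithm is well defined) and, at each interior vertex, a signed
relative turning angle α_t in degrees on (−180, 180].  The observation
for step t pairs the speed of that step with the turning angle at the
vertex it shares with step t−1; the first step of a track therefore has
no angle, and its emission uses the speed factor alone.

Speeds across a gap-closed frame jump divide by the true elapsed time
(frame difference × dt).  The turning angles touching a gap are marked
absent by default, because the intermediate geometry is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import Track

__all__ = ["ObservationSequence", "compute_observables", "downsample"]

#: floor applied to dimensionless speed before taking logarithms
IOTA_FLOOR = 1e-9


@dataclass(frozen=True)
class ObservationSequence:
    """Per-step observables of one track.

    Attributes
    ----------
    iota : ndarray, shape (n_steps,)
        Dimensionless instantaneous speed, >= 0.
    alpha_deg : ndarray, shape (n_steps,)
        Signed turning angle in degrees on (−180, 180], aligned so that
        ``alpha_deg[t]`` is the angle between steps t−1 and t.  NaN
        where absent; index 0 is always absent.
    has_angle : ndarray of bool, shape (n_steps,)
        True where ``alpha_deg`` is defined.
    """

    iota: np.ndarray
    alpha_deg: np.ndarray
    has_angle: np.ndarray

    def __post_init__(self) -> None:
        iota = np.asarray(self.iota, dtype=np.float64)
        alpha = np.asarray(self.alpha_deg, dtype=np.float64)
        has = np.asarray(self.has_angle, dtype=bool)
        if not (len(iota) == len(alpha) == len(has)):
            raise ValueError("iota, alpha_deg and has_angle must have equal length")
        if len(iota) == 0:
            raise ValueError("empty observation sequence")
        if np.any(iota < 0):
            raise ValueError("speeds must be non-negative")
        if has[0]:
            raise ValueError("the first step cannot carry an angle")
        valid = alpha[has]
        if np.any((valid <= -180.0) | (valid > 180.0)):
            raise ValueError("angles must lie in (-180, 180]")
        object.__setattr__(self, "iota", iota)
        object.__setattr__(self, "alpha_deg", alpha)
        object.__setattr__(self, "has_angle", has)

    @property
    def n_steps(self) -> int:
        return len(self.iota)

    def __len__(self) -> int:
        return len(self.iota)


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle (degrees) turning from vectors u to v, on (−180, 180]."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 returns [-180, 180]; fold the closed lower end onto +180
    ang[ang == -180.0] = 180.0
    return ang


def compute_observables(track: Track, keep_gap_angles: bool = False) -> ObservationSequence:
    """Extract dimensionless speeds and turning angles from a track.

    Parameters
    ----------
    track : Track
        At least 2 positions; 3 are needed for any angle to exist.
    keep_gap_angles : bool
        If False (default), angles at vertices adjacent to a frame gap
        are marked absent.  Speeds always use the true elapsed time
        across gaps.

    Notes
    -----
    Zero-length displacements yield ι_t = 0 (floored to a tiny positive
    value inside the emission model) and make the adjacent angles
    undefined.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 positions")
    disp = np.diff(track.positions, axis=0)
    dframes = np.diff(track.frames)
    elapsed = dframes * track.dt
    dist = np.hypot(disp[:, 0], disp[:, 1])
    iota = dist / elapsed  # already dimensionless: μm/s over 1 μm/s

    n = len(iota)
    alpha = np.full(n, np.nan)
    has = np.zeros(n, dtype=bool)
    if n >= 2:
        u, v = disp[:-1], disp[1:]
        ok = (dist[:-1] > 0) & (dist[1:] > 0)
        if not keep_gap_angles:
            ok &= (dframes[:-1] == 1) & (dframes[1:] == 1)
        ang = np.full(n - 1, np.nan)
        if np.any(ok):
            ang[ok] = _signed_angle_deg(u[ok], v[ok])
        alpha[1:] = ang
        has[1:] = ok
    return ObservationSequence(iota=iota, alpha_deg=alpha, has_angle=has)


def downsample(track: Track, k: int) -> Track:
    """Keep every k-th position of a track, multiplying dt by k.

    Emulates recording the same particle at a k-fold lower frame rate.
    Positions at indices 0, k, 2k, … are retained and re-indexed onto
    consecutive frames with frame interval ``k * dt``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return track
    positions = track.positions[::k]
    if len(positions) < 2:
        raise ValueError("downsampling leaves fewer than 2 positions")
    return Track(
        track_id=track.track_id,
        frames=np.arange(len(positions), dtype=np.int64),
        positions=positions,
        dt=track.dt * k,
        cell_id=track.cell_id,
        condition=track.condition,
    )
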