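"""Ensemble mean squared displacement and anomalous-exponent fitting.

The per-cell MSD is the ensemble (from-origin) average

    MSD(t) = (1/N) Σ_i (x_{i,t} − x_{i,0})²,

over the N tracks of one cell that reach lag t, not the time-averaged
MSD (a time-averaged variant is available behind a flag for
comparison).  Anomalous diffusion is quantified by fitting the power
law MSD(t) ~ t^α by ordinary least squares in log-log space; α < 1
indicates subdiffusion, α = 1 Brownian motion, α > 1 superdiffusion
(e.g. a directed component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from .tracks import Track

__all__ = ["MSDResult", "msd_curve", "fit_alpha"]


@dataclass
class MSDResult:
    """MSD curve of one cell, optionally with a fitted exponent."""

    lags: np.ndarray       # seconds, starting at 0
    msd: np.ndarray        # μm², same length
    n_tracks: np.ndarray   # tracks contributing per lag
    cell_id: str = "cell0"
    alpha_msd: float | None = None
    fit_range: tuple[float, float] | None = None


def msd_curve(
    tracks: Sequence[Track],
    max_lag: float,
    cell_id: str | None = None,
    time_averaged: bool = False,
) -> MSDResult:
    """Ensemble MSD over the tracks of one cell.

    Each track contributes its squared displacement from its own first
    position at every lag it is long enough to reach.  Tracks with
    frame gaps skip the lags whose target frame was not observed.

    Parameters
    ----------
    tracks : sequence of Track
        All sharing the same frame interval (pre-filter by length
        upstream, e.g. with :func:`pextrack.tracks.filter_min_steps`).
    max_lag : float
        Largest lag in seconds.
    time_averaged : bool
        If True, average over all start points within each track
        instead of using only the track origin (off by default; the
        from-origin form is the primary definition here).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    if not max_lag > 0:
        raise ValueError("max_lag must be positive")
    dts = {t.dt for t in tracks}
    if len(dts) != 1:
        raise ValueError("tracks have differing dt")
    dt = dts.pop()
    max_m = int(np.floor(max_lag / dt + 1e-9))
    if max_m < 1:
        raise ValueError("max_lag is shorter than one frame interval")

    sums = np.zeros(max_m + 1)
    counts = np.zeros(max_m + 1, dtype=np.int64)
    counts[0] = len(tracks)
    for t in tracks:
        rel = t.frames - t.frames[0]
        if time_averaged:
            index = {int(f): i for i, f in enumerate(rel)}
            for m in range(1, max_m + 1):
                d2, n = 0.0, 0
                for f0, i0 in index.items():
                    i1 = index.get(f0 + m)
                    if i1 is not None:
                        diff = t.positions[i1] - t.positions[i0]
                        d2 += float(diff @ diff)
                        n += 1
                if n:
                    sums[m] += d2 / n
                    counts[m] += 1
        else:
            here = np.isin(np.arange(1, max_m + 1), rel)
            idx = {int(f): i for i, f in enumerate(rel)}
            for m in np.nonzero(here)[0] + 1:
                diff = t.positions[idx[int(m)]] - t.positions[0]
                sums[m] += float(diff @ diff)
                counts[m] += 1

    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    msd[0] = 0.0
    if not np.any(counts[1:] > 0):
        raise ValueError("no track reaches any positive lag")
    return MSDResult(
        lags=np.arange(max_m + 1) * dt,
        msd=msd,
        n_tracks=counts,
        cell_id=cell_id if cell_id is not None else tracks[0].cell_id,
    )


def fit_alpha(result: MSDResult, fit_range: tuple[float, float] = (0.1, 20.0)) -> float:
    """Fit the anomaly exponent α of MSD(t) ~ t^α.

    Ordinary least squares of log MSD against log t over the lags
    inside ``fit_range`` (lag 0 is excluded by construction; lags with
    zero or missing MSD are dropped).  The fitted α and range are
    stored on ``result`` and returned.
    """
    lo, hi = fit_range
    mask = (
        (result.lags >= lo - 1e-12)
        & (result.lags <= hi + 1e-12)
        & (result.lags > 0)
        & np.isfinite(result.msd)
        & (result.msd > 0)
    )
    if mask.sum() < 2:
        raise ValueError("need at least 2 positive MSD values inside the fit range")
    X = np.log(result.lags[mask])[:, None]
    y = np.log(result.msd[mask])
    alpha = float(LinearRegression().fit(X, y).coef_[0])
    result.alpha_msd = alpha
    result.fit_range = (lo, hi)
    return alpha
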