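"""End-to-end workflows: simulation validation and track-study runs.

Two entry points mirror the package's intended use:

``run_validation``
    Simulate switching-mode tracks with known states, fit the full HMM
    to each track, Viterbi-decode, and score the decoding against the
    ground truth, including the speed-parameter perturbation curve.

``run_study``
    The two-stage protocol for real data: stage 1 fits all HMM
    parameters on a designated set of mixed-mode tracks and averages
    the emission parameters; stage 2 freezes the emissions and fits
    only occupancy π and transition matrix T per track, decodes states,
    aggregates per cell, and compares conditions.

All randomness flows from one seed; every output dictionary embeds the
seed and settings used so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    aggregate_per_cell,
    compare_conditions,
    perturbation_experiment,
    run_ratio_curve,
    summarize_validation,
)
from .hmm import HMMParams, TwoStateHMM, baum_welch, viterbi
from .msd import fit_alpha, msd_curve
from .observables import compute_observables
from .simulator import SimParams, simulate_dataset
from .tracks import TrackSet, filter_min_steps

logger = logging.getLogger("pextrack")

__all__ = [
    "fit_tracks_full",
    "fit_emissions",
    "scan_tracks",
    "run_validation",
    "run_study",
]

EMISSION_GROUPS = ("mu_iota", "sigma_iota", "sigma_alpha2")


def fit_tracks_full(ts: TrackSet, tol: float = 1e-6, max_iter: int = 500):
    """Fit all HMM parameters independently to every track.

    Returns (params_by_id, states_by_id, obs_by_id): fitted parameters,
    Viterbi state path and observables for each track.
    """
    params, states, obs_map = {}, {}, {}
    for t in ts:
        obs = compute_observables(t)
        res = baum_welch(obs, tol=tol, max_iter=max_iter)
        params[t.track_id] = res.params
        states[t.track_id] = viterbi(obs, res.params)
        obs_map[t.track_id] = obs
    return params, states, obs_map


def fit_emissions(
    ts: TrackSet,
    track_ids: Sequence[str] | None = None,
    mode: str = "per_track_average",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMParams:
    """Stage 1: estimate the shared emission parameters.

    Parameters
    ----------
    ts : TrackSet
    track_ids : sequence of str, optional
        The designated mixed-mode tracks; all tracks when omitted.
    mode : {"per_track_average", "joint"}
        Fit each track separately and average the emission parameters
        (default), or fit one parameter set jointly on all sequences.

    Returns
    -------
    HMMParams with the averaged (or joint) emissions; π and T are
    averaged too but are refit per track in stage 2.
    """
    sel = ts if track_ids is None else ts.subset(track_ids)
    if len(sel) == 0:
        raise ValueError("no tracks selected for the emission fit")
    obs_list = [compute_observables(t) for t in sel]
    if mode == "joint":
        return baum_welch(obs_list, tol=tol, max_iter=max_iter).params
    if mode != "per_track_average":
        raise ValueError("mode must be 'per_track_average' or 'joint'")
    fits = [baum_welch(o, tol=tol, max_iter=max_iter).params for o in obs_list]
    return HMMParams(
        mu_iota=np.mean([f.mu_iota for f in fits], axis=0),
        sigma_iota=np.mean([f.sigma_iota for f in fits], axis=0),
        sigma_alpha2=float(np.mean([f.sigma_alpha2 for f in fits])),
        pi=np.mean([f.pi for f in fits], axis=0),
        T=np.mean([f.T for f in fits], axis=0),
    )


def scan_tracks(ts: TrackSet, emissions: HMMParams, tol: float = 1e-6, max_iter: int = 500):
    """Stage 2: per-track {π, T} fit with frozen emissions, then decode.

    Returns (per_track DataFrame, states_by_id).
    """
    model = TwoStateHMM(
        mu_iota=emissions.mu_iota,
        sigma_iota=emissions.sigma_iota,
        sigma_alpha2=emissions.sigma_alpha2,
        frozen=EMISSION_GROUPS,
        tol=tol,
        max_iter=max_iter,
    )
    rows, states = [], {}
    for t in ts:
        obs = compute_observables(t)
        fitted = model.fit(obs)
        p = fitted.params_
        states[t.track_id] = fitted.predict(obs)
        rows.append(
            {
                "condition": t.condition,
                "cell_id": t.cell_id,
                "track_id": t.track_id,
                "pi1": p.pi[0],
                "pi2": p.pi[1],
                "T11": p.T[0, 0],
                "T12": p.T[0, 1],
                "T21": p.T[1, 0],
                "T22": p.T[1, 1],
                "loglik": fitted.loglik_trace_[-1],
                "n_iter": fitted.n_iter_,
            }
        )
    return pd.DataFrame(rows), states


# ---------------------------------------------------------------------------
# Workflows
# ---------------------------------------------------------------------------


def run_validation(
    sim_params: SimParams | None = None,
    sigma_levels: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.5),
    n_reps: int = 20,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulation-validation workflow.

    Simulates a labeled dataset, runs an unconstrained per-track
    Baum-Welch fit plus Viterbi decoding, scores the decoding against
    the generative states, and measures decoding robustness to noise on
    the fitted speed locations.

    Returns a dictionary with the validation summary, the across-track
    averages of the fitted parameters, and the perturbation table; if
    ``out_dir`` is given, the tables are also written as CSV/JSON.
    """
    p = sim_params if sim_params is not None else SimParams()
    if seed is not None:
        p = dataclasses.replace(p, seed=seed)
    logger.info("simulating %d tracks x %d steps", p.n_tracks, p.n_steps)
    ts, truth = simulate_dataset(p)
    params, states, obs_map = fit_tracks_full(ts)
    ids = [t.track_id for t in ts]
    summary = summarize_validation([truth[i] for i in ids], [states[i] for i in ids])
    mu = np.array([params[i].mu_iota for i in ids])
    sigma = np.array([params[i].sigma_iota for i in ids])
    T = np.array([params[i].T for i in ids])
    rng = np.random.default_rng(np.random.SeedSequence(p.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    perturb = perturbation_experiment(
        [obs_map[i] for i in ids],
        [truth[i] for i in ids],
        [params[i] for i in ids],
        sigma_levels,
        n_reps,
        rng,
    )
    result = {
        "seed": p.seed,
        "sim_params": p.to_dict(),
        "validation": summary,
        "mean_mu_iota": mu.mean(axis=0).tolist(),
        "sd_mu_iota": mu.std(axis=0).tolist(),
        "mean_sigma_iota": sigma.mean(axis=0).tolist(),
        "mean_T": T.mean(axis=0).tolist(),
        "se_T12": float(T[:, 0, 1].std(ddof=1) / np.sqrt(len(ids))),
        "se_T21": float(T[:, 1, 0].std(ddof=1) / np.sqrt(len(ids))),
        "perturbation": perturb.to_dict(orient="list"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_summary.json").write_text(json.dumps(result, indent=2))
        perturb.to_csv(out / "perturbation.csv", index=False)
        _write_states_csv(states, out / "decoded_states.csv")
    return result


def run_study(
    ts: TrackSet,
    stage1_track_ids: Sequence[str] | None = None,
    emissions: HMMParams | None = None,
    min_steps: int = 50,
    max_lag: float = 20.0,
    msd_fit_range: tuple[float, float] | None = None,
    k_max: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
    out_dir: str | Path | None = None,
) -> dict:
    """Two-stage study workflow on a (possibly multi-condition) TrackSet.

    Filters tracks by length, obtains emissions (stage 1, unless
    supplied), runs the stage-2 per-track {π, T} scan with Viterbi
    decoding, aggregates π/T per cell, computes per-condition
    directed-run ratio curves with bootstrap CIs, pairwise per-cell π₂
    comparisons across conditions (Bonferroni over all pairs), and
    per-cell MSD curves with fitted anomaly exponents.
    """
    ts = filter_min_steps(ts, min_steps)
    if len(ts) == 0:
        raise ValueError("no track passes the length filter")
    rng = np.random.default_rng(seed)
    if emissions is None:
        emissions = fit_emissions(ts, stage1_track_ids)
    per_track, states = scan_tracks(ts, emissions)
    per_cell = aggregate_per_cell(per_track)

    conditions = ts.conditions()
    run_curves = {}
    for cond in conditions:
        ids = [t.track_id for t in ts if t.condition == cond]
        run_curves[cond] = run_ratio_curve(
            [states[i] for i in ids], k_max=k_max, n_boot=n_boot, rng=rng
        )

    pairs = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]]
    comparisons = {}
    m = max(len(pairs), 1)
    for a, b in pairs:
        va = per_cell.loc[per_cell["condition"] == a, "pi2"]
        vb = per_cell.loc[per_cell["condition"] == b, "pi2"]
        if len(va) >= 2 and len(vb) >= 2:
            c = compare_conditions(va, vb, m_comparisons=m, equal_var=equal_var)
            comparisons[f"{a}_vs_{b}"] = {"statistic": c.statistic, "p": c.p, "q": c.q, "m": c.m}

    msd_rows = []
    fit_range = msd_fit_range if msd_fit_range is not None else (min(0.1, max_lag / 10), max_lag)
    for cond in conditions:
        for cell, tracks in ts.by_cell(cond).items():
            try:
                res = msd_curve(tracks, max_lag=max_lag, cell_id=cell)
                alpha = fit_alpha(res, fit_range)
            except ValueError:
                continue
            msd_rows.append({"condition": cond, "cell_id": cell, "alpha_msd": alpha})
    msd_summary = pd.DataFrame(msd_rows)

    result = {
        "seed": seed,
        "emissions": emissions.to_dict(),
        "n_tracks": len(ts),
        "per_track": per_track,
        "per_cell": per_cell,
        "run_curves": run_curves,
        "comparisons": comparisons,
        "msd_summary": msd_summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_track.to_csv(out / "per_track_params.csv", index=False)
        per_cell.to_csv(out / "per_cell_params.csv", index=False)
        msd_summary.to_csv(out / "msd_summary.csv", index=False)
        for cond, curve in run_curves.items():
            curve.to_csv(out / f"run_ratio_{cond}.csv", index=False)
        (out / "study_summary.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "emissions": emissions.to_dict(),
                    "n_tracks": len(ts),
                    "comparisons": comparisons,
                },
                indent=2,
            )
        )
        _write_states_csv(states, out / "decoded_states.csv")
    return result


def _write_states_csv(states: Mapping[str, np.ndarray], path: Path) -> None:
    rows = [
        (tid, step, int(s) + 1)
        for tid, seq in states.items()
        for step, s in enumerate(seq)
    ]
    pd.DataFrame(rows, columns=["track_id", "step", "state"]).to_csv(path, index=False)
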