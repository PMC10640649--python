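"""Validation metrics, sensitivity analysis and condition statistics.

The directed state s2 is the positive class throughout.  Besides the
conventional F1 = 2PR/(P+R), the variant PR/(P+R) without the factor 2
is reported as ``f1_as_printed`` for comparability with analyses that
use that form; the conventional value is the default everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import HMMParams, viterbi
from .observables import ObservationSequence

__all__ = [
    "ValidationReport",
    "ConditionComparison",
    "classification_metrics",
    "summarize_validation",
    "perturbation_experiment",
    "max_run_length",
    "run_ratio_curve",
    "aggregate_per_cell",
    "compare_conditions",
]


@dataclass(frozen=True)
class ValidationReport:
    """Step-level confusion counts and derived scores (s2 positive)."""

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    precision: float
    f1: float
    f1_as_printed: float
    accuracy: float
    undefined: bool  # True when a zero denominator forced a score to 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classification_metrics(truth: np.ndarray, pred: np.ndarray) -> ValidationReport:
    """Score a decoded state sequence against ground truth.

    recall = TP/(TP+FN), precision = TP/(TP+FP); ratios with a zero
    denominator are reported as 0 with the ``undefined`` flag set.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    undefined = False
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, True
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
        f1_printed = precision * recall / (precision + recall)
    else:
        f1 = f1_printed = 0.0
        undefined = True
    if undefined:
        warnings.warn("zero denominator in a classification score; reported as 0")
    accuracy = float(np.mean(truth == pred))
    return ValidationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        recall=recall, precision=precision,
        f1=f1, f1_as_printed=f1_printed,
        accuracy=accuracy, undefined=undefined,
    )


def summarize_validation(
    truths: Sequence[np.ndarray], preds: Sequence[np.ndarray]
) -> dict[str, float]:
    """Pooled confusion scores plus the mean of per-track accuracies."""
    per_track_acc = [float(np.mean(np.asarray(t) == np.asarray(p))) for t, p in zip(truths, preds)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = classification_metrics(np.concatenate(truths), np.concatenate(preds))
    return {
        "mean_per_track_accuracy": float(np.mean(per_track_acc)),
        "pooled_accuracy": pooled.accuracy,
        "recall": pooled.recall,
        "precision": pooled.precision,
        "f1": pooled.f1,
        "f1_as_printed": pooled.f1_as_printed,
        "n_tracks": float(len(per_track_acc)),
    }


# ---------------------------------------------------------------------------
# Sensitivity of decoding to speed-parameter perturbation
# ---------------------------------------------------------------------------


def perturbation_experiment(
    obs_list: Sequence[ObservationSequence],
    truths: Sequence[np.ndarray],
    params_list: Sequence[HMMParams],
    sigma_levels: Sequence[float],
    n_reps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Decoding robustness against noise on the fitted speed locations.

    For each noise level σ and repetition, independent normal(0, σ)
    perturbations are added to both entries of each track's fitted
    μ_ι before re-decoding with Viterbi; the pooled F1 against ground
    truth is averaged over repetitions.  σ = 0 reproduces the
    unperturbed decoding exactly.

    Returns
    -------
    DataFrame with columns ``sigma``, ``mean_f1``, ``sd_f1``.
    """
    if len(obs_list) != len(truths) or len(obs_list) != len(params_list):
        raise ValueError("obs_list, truths and params_list must align")
    rows = []
    for sigma in sigma_levels:
        f1s = []
        reps = 1 if sigma == 0 else n_reps
        for _ in range(reps):
            preds = []
            for obs, params in zip(obs_list, params_list):
                if sigma > 0:
                    mu = params.mu_iota + rng.normal(0.0, sigma, size=2)
                    params = HMMParams(
                        mu_iota=mu,
                        sigma_iota=params.sigma_iota,
                        sigma_alpha2=params.sigma_alpha2,
                        pi=params.pi,
                        T=params.T,
                    )
                preds.append(viterbi(obs, params))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = classification_metrics(np.concatenate(truths), np.concatenate(preds))
            f1s.append(rep.f1)
        rows.append((float(sigma), float(np.mean(f1s)), float(np.std(f1s))))
    return pd.DataFrame(rows, columns=["sigma", "mean_f1", "sd_f1"])


# ---------------------------------------------------------------------------
# Consecutive directed-run statistics
# ---------------------------------------------------------------------------


def max_run_length(states: np.ndarray, state: int = 1) -> int:
    """Longest run of consecutive steps spent in ``state``."""
    best = run = 0
    for s in np.asarray(states):
        run = run + 1 if s == state else 0
        best = max(best, run)
    return best


def run_ratio_curve(
    state_seqs: Sequence[np.ndarray],
    k_max: int,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Fraction of tracks with at least k consecutive directed steps.

    For k = 1..k_max the ratio of tracks whose longest s2 run reaches
    k, with percentile-bootstrap confidence bounds obtained by
    resampling tracks with replacement.  The curve is non-increasing in
    k by construction.

    Returns
    -------
    DataFrame with columns ``k``, ``ratio``, ``ci_low``, ``ci_high``.
    """
    if not state_seqs:
        raise ValueError("no state sequences given")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    runs = np.array([max_run_length(s) for s in state_seqs])
    n = len(runs)
    ks = np.arange(1, k_max + 1)
    ratio = np.array([np.mean(runs >= k) for k in ks])
    boot = np.empty((n_boot, k_max))
    for b in range(n_boot):
        sample = runs[rng.integers(0, n, size=n)]
        boot[b] = [np.mean(sample >= k) for k in ks]
    lo = np.quantile(boot, (1 - ci) / 2, axis=0)
    hi = np.quantile(boot, 1 - (1 - ci) / 2, axis=0)
    # percentile bounds can exclude the point estimate only through
    # quantile interpolation; clip to keep lo <= ratio <= hi
    lo = np.minimum(lo, ratio)
    hi = np.maximum(hi, ratio)
    return pd.DataFrame({"k": ks, "ratio": ratio, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# Per-cell aggregation and condition comparison
# ---------------------------------------------------------------------------


def aggregate_per_cell(per_track: pd.DataFrame, renormalize: bool = False) -> pd.DataFrame:
    """Average per-track fitted parameters within each cell.

    ``per_track`` needs ``condition`` and ``cell_id`` columns plus
    numeric parameter columns (e.g. pi1, pi2, T11, T12, T21, T22).
    Plain element-wise means preserve row sums of probability vectors;
    ``renormalize`` additionally rescales pi/T rows to sum to exactly
    1, which only matters if the inputs were not normalized.
    """
    value_cols = [c for c in per_track.columns if c not in ("condition", "cell_id", "track_id")]
    out = per_track.groupby(["condition", "cell_id"], sort=True)[value_cols].mean().reset_index()
    if renormalize:
        for pair in (("pi1", "pi2"), ("T11", "T12"), ("T21", "T22")):
            if all(c in out.columns for c in pair):
                s = out[list(pair)].sum(axis=1)
                out[list(pair)] = out[list(pair)].div(s, axis=0)
    return out


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sided t-test with Bonferroni correction."""

    statistic: float
    p: float
    q: float
    m: int


def compare_conditions(
    a: Sequence[float],
    b: Sequence[float],
    m_comparisons: int = 1,
    equal_var: bool = False,
) -> ConditionComparison:
    """Two-sided t-test between per-cell values of two conditions.

    Welch's unequal-variance form by default; ``equal_var=True`` gives
    the classical pooled-variance Student test.  The Bonferroni
    corrected value is q = min(1, m·p).  Two identical constant groups
    give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return ConditionComparison(statistic=t, p=p, q=min(1.0, m_comparisons * p), m=m_comparisons)
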