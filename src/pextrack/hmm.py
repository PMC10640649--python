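"""Two-state hidden Markov model for track-state segmentation.

The hidden states are s1, the random (untethered) migration mode, and
s2, the directed microtubule-bound mode.  Emissions at each step are a
dimensionless speed ι_t, log-normally distributed in both states with
state-specific parameters (μ_ι,i, σ_ι,i), and a turning angle α_t that
is uniform on the circle in s1 and zero-centred normal with standard
deviation σ_α,2 (degrees) in s2, truncated to (−180, 180] and
renormalized.  Speed and angle are conditionally independent given the
state, so the joint emission density factorizes.  Steps without a
defined angle (the first step of every track, vertices adjacent to
gaps or zero displacements) contribute the speed factor only.

Parameters are estimated with the scaled Baum–Welch (EM) algorithm,
states decoded with the Viterbi algorithm.  The state-prior vector π is
interpreted as the overall proportion of steps spent in each state
(occupancy) rather than as a pure initial-state distribution; see
:func:`baum_welch`.

The scikit-learn style estimator :class:`TwoStateHMM` wraps the
functional interface and composes with sklearn tooling (``get_params``
/ ``set_params`` / ``clone``).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .observables import IOTA_FLOOR, ObservationSequence, compute_observables
from .tracks import Track

__all__ = [
    "HMMParams",
    "FitResult",
    "PARAM_GROUPS",
    "speed_logpdf",
    "angle_logpdf",
    "emission_logpdf",
    "emission_log_matrix",
    "posterior_state",
    "forward_backward",
    "baum_welch",
    "viterbi",
    "expected_speed",
    "TwoStateHMM",
]

LOG_UNIFORM_ANGLE = -math.log(360.0)  # per-degree density of the s1 angle model

#: parameter groups that can be frozen during Baum-Welch
PARAM_GROUPS = ("mu_iota", "sigma_iota", "sigma_alpha2", "pi", "T")

SIGMA_IOTA_FLOOR = 1e-3
SIGMA_ALPHA_FLOOR = 0.5  # degrees


@dataclass(frozen=True)
class HMMParams:
    """Full parameter set of the two-state track HMM.

    Attributes
    ----------
    mu_iota, sigma_iota : ndarray, shape (2,)
        Location and scale of the log-normal speed model per state
        (mean and sd of ln ι).
    sigma_alpha2 : float
        Standard deviation (degrees) of the s2 turning-angle normal.
    pi : ndarray, shape (2,)
        State prior / occupancy, sums to 1.
    T : ndarray, shape (2, 2)
        Row-stochastic per-step transition matrix.
    """

    mu_iota: np.ndarray
    sigma_iota: np.ndarray
    sigma_alpha2: float
    pi: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_iota, dtype=np.float64)
        sig = np.asarray(self.sigma_iota, dtype=np.float64)
        pi = np.asarray(self.pi, dtype=np.float64)
        T = np.asarray(self.T, dtype=np.float64)
        if mu.shape != (2,) or sig.shape != (2,) or pi.shape != (2,) or T.shape != (2, 2):
            raise ValueError("parameter shapes must be (2,), (2,), scalar, (2,), (2,2)")
        if np.any(sig <= 0) or not self.sigma_alpha2 > 0:
            raise ValueError("scale parameters must be positive")
        if np.any(pi < 0) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must be a probability vector")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("T must be row-stochastic")
        object.__setattr__(self, "mu_iota", mu)
        object.__setattr__(self, "sigma_iota", sig)
        object.__setattr__(self, "sigma_alpha2", float(self.sigma_alpha2))
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "T", T)

    def relabeled(self) -> "HMMParams":
        """Return parameters with states ordered so μ_ι,1 < μ_ι,2.

        EM is label-symmetric; this fixes s2 as the faster (directed)
        state.
        """
        if self.mu_iota[0] <= self.mu_iota[1]:
            return self
        p = np.array([1, 0])
        return HMMParams(
            mu_iota=self.mu_iota[p],
            sigma_iota=self.sigma_iota[p],
            sigma_alpha2=self.sigma_alpha2,
            pi=self.pi[p],
            T=self.T[np.ix_(p, p)],
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mu_iota": self.mu_iota.tolist(),
            "sigma_iota": self.sigma_iota.tolist(),
            "sigma_alpha2_deg": self.sigma_alpha2,
            "pi": self.pi.tolist(),
            "T": self.T.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            mu_iota=np.asarray(d["mu_iota"]),
            sigma_iota=np.asarray(d["sigma_iota"]),
            sigma_alpha2=float(d["sigma_alpha2_deg"]),
            pi=np.asarray(d["pi"]),
            T=np.asarray(d["T"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitResult:
    """Outcome of a Baum-Welch fit."""

    params: HMMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------


def speed_logpdf(iota, state: int, params: HMMParams):
    """Log density of the log-normal speed model at ι for a state (0 or 1).

    ``lognorm(μ, σ)`` has pdf 1/(ισ√(2π)) exp(−(ln ι − μ)²/(2σ²)) on
    ι > 0; μ and σ are the mean and sd of ln ι.
    """
    iota = np.asarray(iota, dtype=np.float64)
    if np.any(iota <= 0):
        raise ValueError("speed density is defined for iota > 0 only")
    mu = params.mu_iota[state]
    sig = params.sigma_iota[state]
    ln = np.log(iota)
    out = -np.log(iota * sig) - 0.5 * math.log(2 * math.pi) - 0.5 * ((ln - mu) / sig) ** 2
    return out if out.ndim else float(out)


def _log_trunc_norm_const(sigma: float) -> float:
    """log of P(−180 < X <= 180) for X ~ normal(0, sigma)."""
    z = 180.0 / sigma
    # 1 - 2*Phi(-z), computed stably
    return math.log1p(-2.0 * ndtr(-z)) if z < 37 else 0.0


def angle_logpdf(alpha, state: int, params: HMMParams):
    """Log density (per degree) of the turning-angle model.

    s1 (state 0): uniform over the 360° circle.  s2 (state 1):
    normal(0, σ_α,2) truncated to (−180, 180] and renormalized (the
    correction is negligible for σ_α,2 ≪ 180°).  ``alpha=None`` or NaN
    (absent angle) contributes a factor of 1 (log 0) in both states.
    """
    if alpha is None:
        return 0.0
    alpha = np.asarray(alpha, dtype=np.float64)
    absent = np.isnan(alpha)
    if state == 0:
        out = np.where(absent, 0.0, LOG_UNIFORM_ANGLE)
    else:
        sig = params.sigma_alpha2
        val = (
            -math.log(sig)
            - 0.5 * math.log(2 * math.pi)
            - 0.5 * (alpha / sig) ** 2
            - _log_trunc_norm_const(sig)
        )
        out = np.where(absent, 0.0, val)
    return out if out.ndim else float(out)


def emission_logpdf(iota, alpha, state: int, params: HMMParams):
    """Joint emission log density: speed and angle factors multiply."""
    return speed_logpdf(iota, state, params) + angle_logpdf(alpha, state, params)


def emission_log_matrix(obs: ObservationSequence, params: HMMParams) -> np.ndarray:
    """Per-step emission log densities, shape (n_steps, 2)."""
    iota = np.maximum(obs.iota, IOTA_FLOOR)
    logb = np.empty((len(obs), 2))
    for i in range(2):
        logb[:, i] = speed_logpdf(iota, i, params)
        logb[obs.has_angle, i] += angle_logpdf(obs.alpha_deg[obs.has_angle], i, params)
    return logb


def posterior_state(iota, alpha, params: HMMParams) -> np.ndarray:
    """Single-observation state posterior p(s_i | o) via Bayes' theorem.

    Combines the emission densities with the prior π; no temporal
    context is used.  Returns a length-2 probability vector.
    """
    logp = np.array([emission_logpdf(iota, alpha, i, params) for i in range(2)])
    logp += np.log(np.maximum(params.pi, 1e-300))
    logp -= logp.max()
    w = np.exp(logp)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("both emission densities vanish for this observation")
    return w / total


# ---------------------------------------------------------------------------
# Forward-backward / Viterbi
# ---------------------------------------------------------------------------


def forward_backward(
    obs: ObservationSequence, params: HMMParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward recursion.

    Returns
    -------
    gamma : ndarray, shape (T, 2)
        Per-step state posteriors; each row sums to 1.
    xi : ndarray, shape (T-1, 2, 2)
        Per-step joint posteriors of consecutive state pairs.
    loglik : float
        Log of the total path-sum likelihood.

    The forward variables are normalized at every step (scaled
    recursion), so underflow cannot occur for any sequence length; the
    log-likelihood is recovered as the sum of log scale factors.
    """
    logb = emission_log_matrix(obs, params)
    return _forward_backward_from_logb(logb, params.pi, params.T)


def _forward_backward_from_logb(
    logb: np.ndarray, pi: np.ndarray, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    n = logb.shape[0]
    # stabilize each row before exponentiating; the offsets are restored
    # exactly in the log-likelihood via the scale factors
    offset = logb.max(axis=1)
    b = np.exp(logb - offset[:, None])

    alpha = np.empty((n, 2))
    c = np.empty(n)
    a = pi * b[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise FloatingPointError("zero total likelihood at step 0")
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * b[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise FloatingPointError(f"zero total likelihood at step {t}")
        alpha[t] = a / c[t]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.empty((n - 1, 2, 2))
    for t in range(n - 1):
        m = alpha[t][:, None] * T * (b[t + 1] * beta[t + 1])[None, :]
        xi[t] = m / m.sum()

    loglik = float(np.log(c).sum() + offset.sum())
    return gamma, xi, loglik


def viterbi(obs: ObservationSequence, params: HMMParams) -> np.ndarray:
    """Most probable state path (0 = s1 random, 1 = s2 directed).

    Dynamic programming in log space; ties are broken toward s1.
    """
    logb = emission_log_matrix(obs, params)
    n = logb.shape[0]
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logT = np.log(params.T)
    delta = logpi + logb[0]
    back = np.zeros((n, 2), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + logT  # cand[i, j]: come from i into j
        back[t] = np.argmax(cand, axis=0)  # argmax picks s1 on ties
        delta = cand[back[t], [0, 1]] + logb[t]
    path = np.empty(n, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------


def _as_obs_list(
    X: ObservationSequence | Track | Sequence[ObservationSequence | Track],
) -> list[ObservationSequence]:
    if isinstance(X, (ObservationSequence, Track)):
        X = [X]
    out = []
    for x in X:
        if isinstance(x, Track):
            x = compute_observables(x)
        if not isinstance(x, ObservationSequence):
            raise TypeError(f"expected Track or ObservationSequence, got {type(x)!r}")
        out.append(x)
    if not out:
        raise ValueError("no observation sequences given")
    return out


def default_init(obs_list: Sequence[ObservationSequence]) -> HMMParams:
    """Deterministic data-driven initialization for an unconstrained fit.

    μ_ι starts at the 25th/75th percentiles of ln ι (slow/fast), σ_ι at
    the overall spread of ln ι, the angle spread at 30°, occupancy at
    one half and a sticky transition matrix.  No random restarts, so
    repeated fits are bit-identical.
    """
    ln = np.concatenate([np.log(np.maximum(o.iota, IOTA_FLOOR)) for o in obs_list])
    q25, q75 = np.percentile(ln, [25, 75])
    if q75 - q25 < 1e-6:
        q25, q75 = q25 - 0.5, q75 + 0.5
    spread = max(float(np.std(ln)), SIGMA_IOTA_FLOOR)
    return HMMParams(
        mu_iota=np.array([q25, q75]),
        sigma_iota=np.array([spread, spread]),
        sigma_alpha2=30.0,
        pi=np.array([0.5, 0.5]),
        T=np.array([[0.9, 0.1], [0.1, 0.9]]),
    )


def baum_welch(
    X,
    params0: HMMParams | None = None,
    frozen: Iterable[str] = (),
    tol: float = 1e-6,
    max_iter: int = 500,
    pi_update: str = "occupancy",
) -> FitResult:
    """Fit HMM parameters by scaled Baum-Welch (EM).

    Parameters
    ----------
    X : Track, ObservationSequence, or a sequence of them
        Multiple sequences are treated as independent realizations
        sharing one parameter set.
    params0 : HMMParams, optional
        Starting point; a deterministic data-driven initialization is
        used when omitted.
    frozen : iterable of str
        Parameter groups excluded from the M-step, any of
        ``mu_iota, sigma_iota, sigma_alpha2, pi, T``.  Freezing all
        groups evaluates the likelihood without iterating.
    tol : float
        Stop when the log-likelihood improves by less than this.
    max_iter : int
        Iteration cap.
    pi_update : {"occupancy", "initial"}
        Estimator for π.  ``"occupancy"`` (default) interprets π as the
        overall proportion of steps spent in each state: the chain's
        initial distribution is held fixed during fitting (a single
        step contributes negligibly to the likelihood of a long
        sequence) and π is set to the time-averaged posterior occupancy
        Σ_t γ_t(i)/T at convergence.  ``"initial"`` is the textbook
        Baum-Welch M-step, the mean initial-step responsibility γ_0(i),
        updated every iteration; it is degenerate for single sequences.
        Either way π is the single-observation prior of
        :func:`posterior_state` and the initial distribution of
        subsequent decoding.

    Returns
    -------
    FitResult
        With states relabeled so μ_ι,1 < μ_ι,2 whenever ``mu_iota``
        was free (EM is label-symmetric).  ``loglik_trace`` holds the
        per-iteration log-likelihoods of the EM run, which are
        non-decreasing to machine precision; under ``"occupancy"`` the
        final occupancy substitution for π can shift the likelihood of
        the returned parameters marginally relative to the last trace
        entry.
    """
    obs_list = _as_obs_list(X)
    frozen = set(frozen)
    unknown = frozen - set(PARAM_GROUPS)
    if unknown:
        raise ValueError(f"unknown parameter group(s): {sorted(unknown)}")
    if pi_update not in ("occupancy", "initial"):
        raise ValueError("pi_update must be 'occupancy' or 'initial'")
    params = params0 if params0 is not None else default_init(obs_list)

    ln_iota = [np.log(np.maximum(o.iota, IOTA_FLOOR)) for o in obs_list]

    def total_loglik(p: HMMParams) -> float:
        return sum(_forward_backward_from_logb(emission_log_matrix(o, p), p.pi, p.T)[2] for o in obs_list)

    if frozen >= set(PARAM_GROUPS):
        ll = total_loglik(params)
        return FitResult(params=params, loglik_trace=np.array([ll]), n_iter=0, converged=True)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        gammas, xis = [], []
        ll = 0.0
        for o in obs_list:
            g, x, l = _forward_backward_from_logb(emission_log_matrix(o, params), params.pi, params.T)
            gammas.append(g)
            xis.append(x)
            ll += l
        trace.append(ll)

        # M-step
        gamma_all = np.vstack(gammas)
        occ = gamma_all.sum(axis=0)  # responsibility mass per state
        new = {
            "mu_iota": params.mu_iota.copy(),
            "sigma_iota": params.sigma_iota.copy(),
            "sigma_alpha2": params.sigma_alpha2,
            "pi": params.pi.copy(),
            "T": params.T.copy(),
        }
        if "mu_iota" in frozen and "sigma_iota" in frozen:
            pass
        else:
            ln_all = np.concatenate(ln_iota)
            for i in range(2):
                if occ[i] < 1e-10:
                    warnings.warn(f"state {i} received no responsibility mass; keeping its speed parameters")
                    continue
                mu_i = float((gamma_all[:, i] * ln_all).sum() / occ[i])
                if "mu_iota" not in frozen:
                    new["mu_iota"][i] = mu_i
                if "sigma_iota" not in frozen:
                    ref_mu = new["mu_iota"][i]
                    var = float((gamma_all[:, i] * (ln_all - ref_mu) ** 2).sum() / occ[i])
                    new["sigma_iota"][i] = max(math.sqrt(var), SIGMA_IOTA_FLOOR)
        if "sigma_alpha2" not in frozen:
            num = den = 0.0
            for o, g in zip(obs_list, gammas):
                m = o.has_angle
                if np.any(m):
                    num += float((g[m, 1] * o.alpha_deg[m] ** 2).sum())
                    den += float(g[m, 1].sum())
            if den > 1e-10:
                new["sigma_alpha2"] = max(math.sqrt(num / den), SIGMA_ALPHA_FLOOR)
        if "T" not in frozen:
            xi_sum = np.zeros((2, 2))
            gfrom = np.zeros(2)
            for g, x in zip(gammas, xis):
                if len(x):
                    xi_sum += x.sum(axis=0)
                    gfrom += g[:-1].sum(axis=0)
            for i in range(2):
                if gfrom[i] > 1e-10:
                    new["T"][i] = xi_sum[i] / gfrom[i]
            new["T"] = np.clip(new["T"], 0.0, None)
            new["T"] /= new["T"].sum(axis=1, keepdims=True)
        if "pi" not in frozen and pi_update == "initial":
            g0 = np.mean([g[0] for g in gammas], axis=0)
            new["pi"] = g0 / g0.sum()

        params = HMMParams(**new)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    # final E-step: log-likelihood after the last M-step, and fresh
    # responsibilities for the occupancy estimate of pi
    gammas, ll = [], 0.0
    for o in obs_list:
        g, _, l = _forward_backward_from_logb(emission_log_matrix(o, params), params.pi, params.T)
        gammas.append(g)
        ll += l
    trace.append(ll)
    if "pi" not in frozen and pi_update == "occupancy":
        occ = np.vstack(gammas).sum(axis=0)
        params = dataclasses.replace(params, pi=occ / occ.sum())
    if "mu_iota" not in frozen:
        params = params.relabeled()
    return FitResult(params=params, loglik_trace=np.asarray(trace), n_iter=n_iter, converged=converged)


def expected_speed(mu: float, sigma: float) -> float:
    """Mean of a log-normal speed, exp(μ + σ²/2), in μm/s.

    Converts fitted log-domain parameters back to a physical mean speed
    through the 1 μm/s nondimensionalization.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return math.exp(mu + sigma**2 / 2.0)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class TwoStateHMM(BaseEstimator):
    """Scikit-learn style estimator wrapping the two-state track HMM.

    Parameters
    ----------
    mu_iota, sigma_iota : array-like of shape (2,), optional
        Initial (or frozen) log-normal speed parameters.  When omitted
        the fit starts from a deterministic data-driven guess.
    sigma_alpha2 : float
        Initial turning-angle spread of the directed state, degrees.
    pi : array-like of shape (2,), optional
        Initial occupancy vector; default [0.5, 0.5].
    transmat : array-like of shape (2, 2), optional
        Initial transition matrix; default sticky [[0.9,0.1],[0.1,0.9]].
    frozen : tuple of str
        Parameter groups kept fixed during fitting (see
        :data:`PARAM_GROUPS`).  The two-stage protocol freezes
        ``("mu_iota", "sigma_iota", "sigma_alpha2")`` in stage 2.
    tol, max_iter : float, int
        EM stopping rule.
    pi_update : {"occupancy", "initial"}
        M-step variant for π.

    Attributes
    ----------
    params_ : HMMParams
        Fitted parameters.
    loglik_trace_ : ndarray
        Per-iteration log-likelihood (non-decreasing).
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> from pextrack.simulator import SimParams, simulate_dataset
    >>> ts, truth = simulate_dataset(SimParams(n_tracks=3, seed=0))
    >>> model = TwoStateHMM().fit(list(ts))
    >>> states = model.predict(ts.tracks[0])
    """

    def __init__(
        self,
        mu_iota=None,
        sigma_iota=None,
        sigma_alpha2: float = 30.0,
        pi=None,
        transmat=None,
        frozen: tuple = (),
        tol: float = 1e-6,
        max_iter: int = 500,
        pi_update: str = "occupancy",
    ):
        self.mu_iota = mu_iota
        self.sigma_iota = sigma_iota
        self.sigma_alpha2 = sigma_alpha2
        self.pi = pi
        self.transmat = transmat
        self.frozen = frozen
        self.tol = tol
        self.max_iter = max_iter
        self.pi_update = pi_update

    # -- helpers ----------------------------------------------------------
    def _initial_params(self, obs_list) -> HMMParams | None:
        if self.mu_iota is None and self.sigma_iota is None and self.pi is None and self.transmat is None:
            if self.frozen:
                raise ValueError("frozen groups require explicit initial parameters")
            return None
        base = default_init(obs_list)
        return HMMParams(
            mu_iota=np.asarray(self.mu_iota) if self.mu_iota is not None else base.mu_iota,
            sigma_iota=np.asarray(self.sigma_iota) if self.sigma_iota is not None else base.sigma_iota,
            sigma_alpha2=self.sigma_alpha2,
            pi=np.asarray(self.pi) if self.pi is not None else np.array([0.5, 0.5]),
            T=np.asarray(self.transmat) if self.transmat is not None else np.array([[0.9, 0.1], [0.1, 0.9]]),
        )

    def fit(self, X, y=None):
        """Fit by scaled Baum-Welch on one or more tracks/sequences."""
        obs_list = _as_obs_list(X)
        res = baum_welch(
            obs_list,
            params0=self._initial_params(obs_list),
            frozen=self.frozen,
            tol=self.tol,
            max_iter=self.max_iter,
            pi_update=self.pi_update,
        )
        self.params_ = res.params
        self.loglik_trace_ = res.loglik_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("this TwoStateHMM instance is not fitted yet")

    def predict(self, X):
        """Viterbi-decode state labels (0 = random, 1 = directed)."""
        self._check_fitted()
        single = isinstance(X, (Track, ObservationSequence))
        paths = [viterbi(o, self.params_) for o in _as_obs_list(X)]
        return paths[0] if single else paths

    def predict_proba(self, X):
        """Per-step smoothed state posteriors γ from forward-backward."""
        self._check_fitted()
        single = isinstance(X, (Track, ObservationSequence))
        gammas = [forward_backward(o, self.params_)[0] for o in _as_obs_list(X)]
        return gammas[0] if single else gammas

    def score(self, X, y=None) -> float:
        """Total log-likelihood of the sequences under the fitted model."""
        self._check_fitted()
        return sum(forward_backward(o, self.params_)[2] for o in _as_obs_list(X))
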