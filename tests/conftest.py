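import numpy as np
import pytest

from pextrack.simulator import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """10 simulated switching tracks with ground truth (fast fixture)."""
    p = SimParams(n_tracks=10, n_steps=120, seed=42)
    ts, truth = simulate_dataset(p)
    return p, ts, truth


@pytest.fixture(scope="session")
def validation_run():
    """Full simulation-validation run at the default study conditions.

    100 tracks x 200 steps, unconstrained per-track Baum-Welch fits,
    Viterbi decoding and the speed-location perturbation curve.  Shared
    across the acceptance tests that score this run.
    """
    from pextrack.pipeline import run_validation

    return run_validation(seed=1, n_reps=20)


def random_params(rng):
    """A random valid HMMParams draw for oracle comparisons."""
    from pextrack.hmm import HMMParams

    return HMMParams(
        mu_iota=np.sort(rng.uniform(-1.5, 2.5, size=2)),
        sigma_iota=rng.uniform(0.3, 1.5, size=2),
        sigma_alpha2=rng.uniform(10.0, 80.0),
        pi=rng.dirichlet([2.0, 2.0]),
        T=np.vstack([rng.dirichlet([5.0, 2.0]), rng.dirichlet([2.0, 5.0])]),
    )


def random_obs(rng, n, with_absent=True):
    """A random valid ObservationSequence of length n."""
    from pextrack.observables import ObservationSequence

    iota = rng.lognormal(0.5, 1.0, size=n)
    has = np.zeros(n, dtype=bool)
    if n > 1:
        has[1:] = rng.random(n - 1) > (0.3 if with_absent else 0.0)
    alpha = np.full(n, np.nan)
    k = int(has.sum())
    if k:
        a = rng.uniform(-180.0, 180.0, size=k)
        a[a == -180.0] = 180.0
        alpha[has] = a
    return ObservationSequence(iota=iota, alpha_deg=alpha, has_angle=has)
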