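import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp
from sklearn.base import clone

from pextrack.hmm import (
    HMMParams,
    TwoStateHMM,
    angle_logpdf,
    baum_welch,
    emission_logpdf,
    expected_speed,
    forward_backward,
    posterior_state,
    speed_logpdf,
    viterbi,
)
from pextrack.observables import ObservationSequence
from pextrack.simulator import SimParams, simulate_dataset

from conftest import random_obs, random_params


def params_with(**kw):
    base = dict(
        mu_iota=np.array([0.0, 1.0]),
        sigma_iota=np.array([1.0, 0.5]),
        sigma_alpha2=26.0,
        pi=np.array([0.5, 0.5]),
        T=np.array([[0.9, 0.1], [0.1, 0.9]]),
    )
    base.update(kw)
    return HMMParams(**base)


def obs_from(iota, alpha=None):
    iota = np.asarray(iota, dtype=float)
    n = len(iota)
    a = np.full(n, np.nan)
    has = np.zeros(n, dtype=bool)
    if alpha is not None:
        for i, v in enumerate(alpha):
            if v is not None:
                a[i], has[i] = v, True
    return ObservationSequence(iota=iota, alpha_deg=a, has_angle=has)


# ---------------------------------------------------------------------------
# Independent oracles: densities via scipy, likelihood via path enumeration
# ---------------------------------------------------------------------------


def oracle_log_emission(obs, params):
    """Emission log densities built from scipy distributions only."""
    n = len(obs)
    out = np.zeros((n, 2))
    for i in range(2):
        dist = stats.lognorm(s=params.sigma_iota[i], scale=math.exp(params.mu_iota[i]))
        out[:, i] = dist.logpdf(np.maximum(obs.iota, 1e-9))
        for t in range(n):
            if obs.has_angle[t]:
                if i == 0:
                    out[t, i] += stats.uniform(-180, 360).logpdf(obs.alpha_deg[t])
                else:
                    s = params.sigma_alpha2
                    tn = stats.truncnorm(-180 / s, 180 / s, loc=0, scale=s)
                    out[t, i] += tn.logpdf(obs.alpha_deg[t])
    return out


def brute_force_loglik(obs, params):
    """Log path-sum likelihood by explicit enumeration of all 2^T paths."""
    logb = oracle_log_emission(obs, params)
    with np.errstate(divide="ignore"):
        logpi, logT = np.log(params.pi), np.log(params.T)
    terms = []
    for path in itertools.product((0, 1), repeat=len(obs)):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, len(obs)):
            lp += logT[path[t - 1], path[t]] + logb[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def brute_force_viterbi(obs, params):
    """Exhaustive argmax over all paths; ties resolved toward s1 by order."""
    logb = oracle_log_emission(obs, params)
    with np.errstate(divide="ignore"):
        logpi, logT = np.log(params.pi), np.log(params.T)
    best, best_lp = None, -np.inf
    for path in itertools.product((0, 1), repeat=len(obs)):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, len(obs)):
            lp += logT[path[t - 1], path[t]] + logb[t, path[t]]
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------


class TestSpeedLogpdf:
    def test_standard_lognormal_at_one(self):
        p = params_with()
        assert speed_logpdf(1.0, 0, p) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_closed_form_at_median(self):
        p = params_with(mu_iota=np.array([-0.93, 0.06]), sigma_iota=np.array([0.72, 0.50]))
        x = math.exp(-0.93)
        expect = 1.0 / (x * 0.72 * math.sqrt(2 * math.pi))
        assert math.exp(speed_logpdf(x, 0, p)) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.4043, abs=1e-4)

    def test_matches_scipy_lognorm(self):
        p = params_with()
        x = np.array([0.1, 0.5, 1.0, 3.0, 10.0])
        for i in range(2):
            ref = stats.lognorm(s=p.sigma_iota[i], scale=math.exp(p.mu_iota[i])).logpdf(x)
            assert np.allclose(speed_logpdf(x, i, p), ref, atol=1e-12)

    def test_normalized_by_quadrature(self):
        p = params_with()
        for i in range(2):
            val, _ = integrate.quad(lambda x: math.exp(speed_logpdf(x, i, p)), 0, np.inf)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            speed_logpdf(0.0, 0, params_with())


class TestAngleLogpdf:
    def test_uniform_state(self):
        p = params_with()
        for a in (-179.0, 0.0, 45.0, 180.0):
            assert angle_logpdf(a, 0, p) == pytest.approx(math.log(1 / 360), abs=1e-12)

    def test_directed_peak_at_zero(self):
        p = params_with()
        expect = math.log(1 / (26 * math.sqrt(2 * math.pi)))
        assert angle_logpdf(0.0, 1, p) == pytest.approx(expect, abs=1e-9)

    def test_one_sigma_point(self):
        p = params_with()
        assert angle_logpdf(26.0, 1, p) == pytest.approx(angle_logpdf(0.0, 1, p) - 0.5)

    def test_truncation_renormalizes_wide_spread(self):
        p = params_with(sigma_alpha2=120.0)
        val, _ = integrate.quad(lambda a: math.exp(angle_logpdf(a, 1, p)), -180, 180)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_absent_angle_is_unit_factor(self):
        p = params_with()
        assert angle_logpdf(None, 0, p) == 0.0
        assert angle_logpdf(np.nan, 1, p) == 0.0


class TestEmissionLogpdf:
    def test_absent_angle_equals_speed_alone(self):
        p = params_with()
        assert emission_logpdf(2.0, None, 0, p) == speed_logpdf(2.0, 0, p)

    def test_sum_of_factors(self):
        p = params_with()
        got = emission_logpdf(1.0, 10.0, 0, p)
        assert got == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)) + math.log(1 / 360))

    def test_joint_integrates_to_one(self):
        p = params_with()
        for i in range(2):
            val, _ = integrate.dblquad(
                lambda a, x: math.exp(emission_logpdf(x, a, i, p)),
                1e-12, 1000.0, -180.0, 180.0, epsabs=1e-9,
            )
            assert val == pytest.approx(1.0, abs=1e-5)


class TestPosteriorState:
    def test_symmetric_inputs(self):
        p = params_with(mu_iota=np.array([0.0, 0.0]), sigma_iota=np.array([1.0, 1.0]))
        post = posterior_state(1.0, None, p)
        assert post == pytest.approx([0.5, 0.5])

    def test_degenerate_prior(self):
        p = params_with(pi=np.array([1.0, 0.0]))
        assert posterior_state(2.0, 30.0, p) == pytest.approx([1.0, 0.0])

    def test_hand_bayes_arithmetic(self):
        # emission ratio 1:4 against prior 0.8:0.2 balances to 1/2 each;
        # realized by putting the observation at the point where the two
        # lognormal densities have that exact ratio
        p = params_with(pi=np.array([0.8, 0.2]), sigma_iota=np.array([1.0, 1.0]))
        target = math.log(4.0)

        def dens_ratio(x):
            return speed_logpdf(x, 1, p) - speed_logpdf(x, 0, p) - target

        from scipy.optimize import brentq

        x = brentq(dens_ratio, 0.5, 50.0)
        assert posterior_state(x, None, p) == pytest.approx([0.5, 0.5], abs=1e-9)
        # and the implementation agrees with direct Bayes on real densities
        dens = np.array([math.exp(emission_logpdf(1.5, 20.0, i, p)) for i in range(2)])
        direct = p.pi * dens / (p.pi * dens).sum()
        assert posterior_state(1.5, 20.0, p) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# Forward-backward and Viterbi vs enumeration
# ---------------------------------------------------------------------------


class TestForwardBackward:
    def test_length_one_equals_bayes_posterior(self):
        p = params_with()
        obs = obs_from([1.3])
        gamma, xi, ll = forward_backward(obs, p)
        assert gamma[0] == pytest.approx(posterior_state(1.3, None, p))
        dens = [math.exp(emission_logpdf(1.3, None, i, p)) for i in range(2)]
        assert ll == pytest.approx(math.log(p.pi @ np.array(dens)))
        assert xi.shape == (0, 2, 2)

    def test_gamma_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        obs = random_obs(rng, 20)
        gamma, xi, _ = forward_backward(obs, random_params(rng))
        assert np.allclose(gamma.sum(axis=1), 1.0)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0)

    def test_absorbing_chain(self):
        p = params_with(pi=np.array([1.0, 0.0]), T=np.eye(2))
        gamma, _, _ = forward_backward(obs_from([0.5, 1.0, 2.0]), p)
        assert np.allclose(gamma[:, 0], 1.0)

    def test_loglik_matches_enumeration_length3(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        obs = random_obs(rng, 3)
        _, _, ll = forward_backward(obs, p)
        assert ll == pytest.approx(brute_force_loglik(obs, p), abs=1e-9)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_loglik_matches_enumeration_all_lengths(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            p = random_params(rng)
            obs = random_obs(rng, n)
            _, _, ll = forward_backward(obs, p)
            assert abs(ll - brute_force_loglik(obs, p)) < 1e-9

    def test_no_underflow_on_long_sequence(self):
        rng = np.random.default_rng(2)
        obs = random_obs(rng, 5000)
        _, _, ll = forward_backward(obs, random_params(rng))
        assert np.isfinite(ll)


class TestViterbi:
    def test_strong_directed_evidence(self):
        p = params_with(mu_iota=np.array([0.0, 2.3]), sigma_iota=np.array([0.3, 0.1]))
        obs = obs_from([10.0] * 5, [None, 0.0, 1.0, -2.0, 0.5])
        assert np.all(viterbi(obs, p) == 1)

    def test_zero_probability_transitions_pin_path(self):
        p = params_with(pi=np.array([1.0, 0.0]), T=np.eye(2))
        obs = obs_from([10.0, 12.0, 9.0])  # emissions favor s2, chain forbids it
        assert np.all(viterbi(obs, p) == 0)

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_matches_enumeration(self, n):
        rng = np.random.default_rng(200 + n)
        for _ in range(10):
            p = random_params(rng)
            obs = random_obs(rng, n)
            fast = viterbi(obs, p)
            slow, _ = brute_force_viterbi(obs, p)
            assert np.array_equal(fast, slow)


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------


class TestBaumWelch:
    def test_all_frozen_is_evaluation_only(self):
        rng = np.random.default_rng(3)
        p = random_params(rng)
        obs = random_obs(rng, 30)
        res = baum_welch(obs, params0=p, frozen=("mu_iota", "sigma_iota", "sigma_alpha2", "pi", "T"))
        assert res.n_iter == 0
        assert np.array_equal(res.params.mu_iota, p.mu_iota)
        _, _, ll = forward_backward(obs, p)
        assert res.loglik_trace[-1] == pytest.approx(ll)

    def test_loglik_never_decreases(self):
        rng = np.random.default_rng(4)
        obs = random_obs(rng, 150)
        res = baum_welch(obs, params0=random_params(rng), max_iter=50)
        assert np.all(np.diff(res.loglik_trace) >= -1e-8)

    def test_mstep_outputs_satisfy_invariants(self):
        rng = np.random.default_rng(5)
        obs = random_obs(rng, 100)
        res = baum_welch(obs, max_iter=25)
        p = res.params
        assert p.pi.sum() == pytest.approx(1.0)
        assert np.allclose(p.T.sum(axis=1), 1.0)
        assert np.all(p.sigma_iota > 0) and p.sigma_alpha2 > 0
        assert p.mu_iota[0] <= p.mu_iota[1]  # relabeled

    def test_frozen_emissions_stay_fixed(self):
        rng = np.random.default_rng(6)
        obs = random_obs(rng, 120)
        p0 = random_params(rng)
        res = baum_welch(obs, params0=p0, frozen=("mu_iota", "sigma_iota", "sigma_alpha2"))
        assert np.array_equal(res.params.mu_iota, p0.mu_iota)
        assert np.array_equal(res.params.sigma_iota, p0.sigma_iota)
        assert res.params.sigma_alpha2 == p0.sigma_alpha2
        assert not np.array_equal(res.params.T, p0.T)  # these were free

    def test_recovers_generative_speed_means(self, small_dataset):
        from pextrack.observables import compute_observables

        p, ts, truth = small_dataset
        mus = []
        for t in ts:
            res = baum_welch(compute_observables(t))
            mus.append(res.params.mu_iota)
        mu = np.mean(mus, axis=0)
        # the directed mode draws speeds ~ normal(10, 1): E[ln iota] ~ ln 10
        assert mu[1] == pytest.approx(math.log(10.0), abs=0.1)
        # the random mode is an OU process with stationary per-component
        # sd sqrt(5): E[ln |v|] = ln sqrt(5) + (ln 2 - gamma)/2 ~ 0.86,
        # plus a small upward bias from post-switch velocity relaxation
        assert 0.7 < mu[0] < 1.1

    def test_pi_update_modes_differ(self):
        rng = np.random.default_rng(8)
        obs = random_obs(rng, 80)
        occ = baum_welch(obs, max_iter=30, pi_update="occupancy").params.pi
        ini = baum_welch(obs, max_iter=30, pi_update="initial").params.pi
        assert not np.allclose(occ, ini)
        # occupancy equals the time-averaged gamma under the final fit
        assert occ.sum() == pytest.approx(1.0)


class TestExpectedSpeed:
    def test_study_values(self):
        assert round(expected_speed(-0.93, 0.72), 1) == 0.5
        assert round(expected_speed(0.06, 0.50), 1) == 1.2

    def test_point_mass(self):
        assert expected_speed(0.0, 0.0) == 1.0

    def test_matches_lognormal_mean(self):
        assert expected_speed(0.3, 0.8) == pytest.approx(
            stats.lognorm(s=0.8, scale=math.exp(0.3)).mean()
        )


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------


class TestTwoStateHMMEstimator:
    def test_fit_predict_shapes(self, small_dataset):
        _, ts, truth = small_dataset
        model = TwoStateHMM().fit(list(ts))
        assert hasattr(model, "params_")
        paths = model.predict(list(ts))
        assert len(paths) == len(ts)
        assert len(paths[0]) == ts.tracks[0].n_steps
        gamma = model.predict_proba(ts.tracks[0])
        assert gamma.shape == (ts.tracks[0].n_steps, 2)
        assert np.isfinite(model.score(ts.tracks[0]))

    def test_clone_and_get_params_roundtrip(self):
        model = TwoStateHMM(sigma_alpha2=20.0, tol=1e-5, frozen=("pi",))
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            TwoStateHMM().predict([])

    def test_frozen_without_init_params_rejected(self, small_dataset):
        _, ts, _ = small_dataset
        with pytest.raises(ValueError):
            TwoStateHMM(frozen=("mu_iota",)).fit(ts.tracks[0])

    def test_deterministic_refit(self, small_dataset):
        _, ts, _ = small_dataset
        a = TwoStateHMM().fit(ts.tracks[0]).params_
        b = TwoStateHMM().fit(ts.tracks[0]).params_
        assert np.array_equal(a.mu_iota, b.mu_iota)
        assert np.array_equal(a.T, b.T)


class TestParamsSerialization:
    def test_json_roundtrip(self, tmp_path):
        p = params_with()
        p.to_json(tmp_path / "p.json")
        q = HMMParams.from_json(tmp_path / "p.json")
        assert np.array_equal(p.mu_iota, q.mu_iota)
        assert np.array_equal(p.T, q.T)
        assert p.sigma_alpha2 == q.sigma_alpha2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            params_with(pi=np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            params_with(T=np.array([[0.5, 0.6], [0.1, 0.9]]))
        with pytest.raises(ValueError):
            params_with(sigma_iota=np.array([0.0, 1.0]))
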