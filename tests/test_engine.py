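"""MAP estimation, smoothing and sampling on the discretized state space."""

import math

import numpy as np
import pytest

from spikemap.engine import (
    EngineConfig,
    EnumerationError,
    backward_map_pass,
    brute_force_map,
    build_grid,
    emission_logprob,
    exhaustive_spike_marginals,
    forward_collect,
    map_spikes,
    path_log_posterior,
    sample_posterior,
    smoothed_spike_probabilities,
    transition_logprob,
)
from spikemap.model import ModelParams, SpikeTrain, Trace, simulate_trace

FIXED_B = EngineConfig(nc=150, c_max=5.0, nb=1, B_known=1.0)


def small_params(**kw):
    base = dict(A=0.1, tau=1.0, sigma=0.03, eta=0.0, lam=0.2, nmax=3)
    base.update(kw)
    return ModelParams(**base)


class TestTransitionLogprob:
    def test_poisson_no_spike(self):
        p = small_params(lam=0.1)
        assert transition_logprob(0, 0.0, p, 0.01) == pytest.approx(-0.001)

    def test_above_nmax_impossible(self):
        p = small_params(nmax=3)
        assert transition_logprob(4, 0.0, p, 0.01) == -np.inf

    def test_truncated_mass_not_renormalized(self):
        # truncation at nmax keeps the plain Poisson weights
        p = small_params(lam=0.5, nmax=3)
        dt, mu = 0.01, 0.5 * 0.01
        total = sum(math.exp(transition_logprob(n, 0.0, p, dt)) for n in range(4))
        exact = sum(math.exp(-mu) * mu**n / math.factorial(n) for n in range(4))
        assert total == pytest.approx(exact, rel=1e-12)
        assert total < 1.0

    def test_baseline_step_density(self):
        p = small_params(eta=0.02)
        dt, dB = 0.01, 0.001
        s = p.eta * math.sqrt(dt)
        expected = (
            transition_logprob(0, 0.0, p, dt) - 0.5 * (dB / s) ** 2
        )
        got = transition_logprob(0, dB, p, dt)
        # same Gaussian shape around dB=0
        assert got - transition_logprob(0, 0.0, p, dt) == pytest.approx(
            -0.5 * (dB / s) ** 2
        )
        del expected


class TestEmissionLogprob:
    def test_peak_value(self):
        p = small_params(sigma=0.04)
        pred = 1.0
        assert emission_logprob(pred, 0.0, 1.0, p) == pytest.approx(
            -math.log(p.sigma * math.sqrt(2 * math.pi))
        )

    def test_symmetric(self):
        p = small_params(sigma=0.04)
        d = 0.017
        assert emission_logprob(1.0 + d, 0.0, 1.0, p) == pytest.approx(
            emission_logprob(1.0 - d, 0.0, 1.0, p)
        )

    def test_likelihood_ratio_matches_gaussian(self):
        p = small_params(sigma=0.05)
        y = 1.03
        lr = emission_logprob(y, 0.0, 1.0, p) - emission_logprob(y, 1.0, 1.0, p)
        exact = (-0.5 * (y - 1) ** 2 + 0.5 * (y - 1 - p.A) ** 2) / p.sigma**2
        assert lr == pytest.approx(exact, abs=1e-12)


class TestBackwardForward:
    def test_single_frame_is_emission_only(self):
        p = small_params()
        tr = Trace(values=np.array([1.02]), dt=0.01)
        grid = build_grid(tr, p, FIXED_B)
        ms, _, _ = backward_map_pass(tr, p, grid)
        emis = emission_logprob(1.02, grid.c_values, 1.0, p)
        assert np.allclose(ms[0][:, 0], emis, rtol=1e-5, atol=1e-4)

    def test_huge_noise_yields_no_spikes(self):
        p = small_params(sigma=5.0, lam=0.1)
        st = SpikeTrain(times=np.array([0.5]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 2.0, 0.02, seed=0)
        res = map_spikes(tr, p, FIXED_B)
        assert res.counts.sum() == 0

    def test_constant_trace_yields_no_spikes(self):
        p = small_params()
        tr = Trace(values=np.ones(100), dt=0.01)
        res = map_spikes(tr, p, FIXED_B)
        assert res.counts.sum() == 0

    def test_noiseless_single_spike_exact_inverse(self):
        p = small_params()
        st = SpikeTrain(times=np.array([0.81]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 2.0, 0.02, seed=0)
        res = map_spikes(tr, p.with_(sigma=0.005), FIXED_B)
        assert np.array_equal(res.counts, st.counts(100, 0.02))
        assert np.allclose(res.path.B, 1.0)

    def test_counts_capped_at_nmax(self):
        p = small_params(nmax=2, lam=5.0, sigma=0.05)
        st = SpikeTrain(times=np.array([0.5] * 5))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 1.5, 0.05, seed=0)
        res = map_spikes(tr, p, FIXED_B)
        assert res.counts.max() <= 2

    def test_unknown_flat_baseline_recovered(self):
        """A flat baseline at 0.7 (not told to the engine) is estimated."""
        p = small_params(sigma=0.02)
        st = SpikeTrain(times=np.array([1.0]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 3.0, 0.02, seed=1, B1=0.7)
        noisy = Trace(tr.values + 0.01 * np.random.default_rng(2).standard_normal(len(tr)), tr.dt)
        res = map_spikes(noisy, p.with_(sigma=0.01), EngineConfig(nc=100, nb=80))
        assert np.all(np.abs(res.path.B[20:] - 0.7) < 0.02 * 0.7)
        assert res.counts.sum() == 1

    def test_map_log_posterior_beats_projected_truth(self):
        """The MAP path scores at least as high as the true path."""
        p = small_params(sigma=0.04, lam=0.5)
        rng = np.random.default_rng(3)
        for trial in range(5):
            counts = np.minimum(rng.poisson(0.1, size=40), 3)
            counts[0] = 0
            st = SpikeTrain.from_counts(counts, 0.05)
            tr, _ = simulate_trace(st, p.with_(sigma=0.0), 2.0, 0.05,
                                   seed=int(rng.integers(1 << 30)))
            noisy = Trace(tr.values + p.sigma * rng.standard_normal(40), 0.05)
            res = map_spikes(noisy, p, EngineConfig(nc=150, c_max=5.0, nb=1,
                                                    B_known=1.0, c1=0.0))
            lp_true = path_log_posterior(noisy, p, counts, 0.0, np.ones(40))
            assert res.log_posterior >= lp_true - 1e-9

    def test_non_finite_trace_rejected(self):
        p = small_params()
        bad = Trace(values=np.ones(10), dt=0.01)
        bad.values[3] = np.inf  # corrupt after construction
        with pytest.raises(ValueError):
            map_spikes(bad, p, FIXED_B)


class TestOracleEquivalence:
    """Grid estimator vs exhaustive enumeration on small instances."""

    PARAMS = ModelParams(A=0.1, tau=1.0, sigma=0.05, eta=0.0, lam=1.0, nmax=2)
    CFG = EngineConfig(nc=801, c_max=8.0, c_spacing="linear", nb=1, B_known=1.0, c1=0.0)

    def _instance(self, rng, T=12, dt=0.1):
        counts = np.minimum(rng.poisson(0.3, size=T), 2)
        counts[0] = 0
        st = SpikeTrain.from_counts(counts, dt)
        tr, _ = simulate_trace(st, self.PARAMS, T * dt, dt,
                               seed=int(rng.integers(1 << 30)))
        return tr

    def test_map_agrees_with_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tr = self._instance(rng)
            res = map_spikes(tr, self.PARAMS, self.CFG)
            bf = brute_force_map(tr, self.PARAMS, c1_values=0.0, B_values=1.0,
                                 c_cap=8.0)
            assert np.array_equal(res.counts, bf.counts)
            assert res.log_posterior == pytest.approx(bf.log_posterior, abs=1e-6)

    def test_map_agrees_with_free_initial_calcium(self):
        """Uniform-grid prior on c_1: enumeration over the same grid."""
        params = self.PARAMS
        cfg = EngineConfig(nc=121, c_max=3.0, c_spacing="linear", nb=1,
                           B_known=1.0)
        rng = np.random.default_rng(12)
        for _ in range(10):
            counts = np.minimum(rng.poisson(0.3, size=8), 2)
            st = SpikeTrain.from_counts(counts, 0.1)
            tr, _ = simulate_trace(st, params, 0.8, 0.1,
                                   seed=int(rng.integers(1 << 30)), c1=0.6)
            res = map_spikes(tr, params, cfg)
            grid = build_grid(tr, params, cfg)
            bf = brute_force_map(tr, params, c1_values=grid.c_values,
                                 B_values=1.0, c_cap=3.0)
            assert np.array_equal(res.counts, bf.counts)
            assert abs(res.path.c[0] - bf.path.c[0]) < 1e-9

    def test_marginals_agree_with_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tr = self._instance(rng)
            post = smoothed_spike_probabilities(tr, self.PARAMS, self.CFG)
            em = exhaustive_spike_marginals(tr, self.PARAMS, c1_values=0.0,
                                            B_values=1.0, c_cap=8.0)
            assert np.max(np.abs(post.spike_marginals - em)) < 1e-6


class TestSmoothing:
    def test_isolated_spike_marginal(self):
        p = small_params(sigma=0.01)
        st = SpikeTrain(times=np.array([0.51]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 1.5, 0.05, seed=0)
        post = smoothed_spike_probabilities(tr, p, FIXED_B)
        k = 10  # bin containing the spike (0.5, 0.55]
        assert post.spike_marginals[k, 1] > 0.98
        off = np.delete(post.spike_marginals[:, 1:].sum(axis=1), k)
        assert np.all(off < 0.02)

    def test_marginals_normalized(self):
        p = small_params(sigma=0.05)
        tr, _ = simulate_trace(SpikeTrain(times=np.array([0.3])),
                               p.with_(sigma=0.0), 1.0, 0.05, seed=1)
        post = smoothed_spike_probabilities(tr, p, FIXED_B)
        assert np.allclose(post.spike_marginals.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(post.alpha.sum(axis=(1, 2)), 1.0, atol=1e-9)


class TestSampling:
    def test_noiseless_samples_all_equal_truth(self):
        p = small_params(sigma=0.004)
        counts_true = np.zeros(30, dtype=int)
        counts_true[[7, 19]] = 1
        st = SpikeTrain.from_counts(counts_true, 0.05)
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 1.5, 0.05, seed=0)
        samples = sample_posterior(tr, p, FIXED_B, n_samples=50, seed=1)
        for s, _ in samples:
            assert np.array_equal(s.counts(30, 0.05), counts_true)

    def test_frequencies_match_marginals(self):
        p = small_params(sigma=0.04, lam=0.5, nmax=2)
        st = SpikeTrain(times=np.array([0.4, 1.1, 2.2]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 3.0, 0.05, seed=3)
        cfg = EngineConfig(nc=150, c_max=5.0, nb=1, B_known=1.0)
        post = smoothed_spike_probabilities(tr, p, cfg)
        samples = sample_posterior(tr, p, cfg, n_samples=2000, seed=9)
        T = len(tr)
        freq = np.zeros((T, p.nmax + 1))
        for s, _ in samples:
            cnt = np.minimum(s.counts(T, tr.dt), p.nmax)
            freq[np.arange(T), cnt] += 1
        freq /= len(samples)
        assert np.max(np.abs(freq - post.spike_marginals)) < 0.05

    def test_seed_reproducible(self):
        p = small_params(sigma=0.03)
        tr, _ = simulate_trace(SpikeTrain(times=np.array([0.5])),
                               p.with_(sigma=0.0), 1.0, 0.05, seed=0)
        a = sample_posterior(tr, p, FIXED_B, n_samples=20, seed=5)
        b = sample_posterior(tr, p, FIXED_B, n_samples=20, seed=5)
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.times, sb.times)


class TestBruteForce:
    def test_constant_trace_no_spikes(self):
        p = small_params(nmax=1)
        tr = Trace(values=np.ones(8), dt=0.1)
        bf = brute_force_map(tr, p, c1_values=0.0, B_values=1.0)
        assert bf.counts.sum() == 0

    def test_search_space_cap(self):
        p = small_params(nmax=3)
        tr = Trace(values=np.ones(30), dt=0.1)
        with pytest.raises(EnumerationError):
            brute_force_map(tr, p, c1_values=0.0, B_values=1.0)


class TestHillRise:
    def test_round_trip(self):
        p = ModelParams(A=0.15, tau=0.8, probe="hill_rise", gamma=0.2,
                        n_hill=2.0, c0=0.1, tau_on=0.05, sigma=0.0, eta=0.0,
                        lam=0.3)
        st = SpikeTrain(times=np.array([1.0, 2.5]))
        tr, _ = simulate_trace(st, p, 5.0, 0.025, seed=1)
        cfg = EngineConfig(nc=60, n_p=30, nb=1, B_known=1.0, c_max=5.0)
        res = map_spikes(tr, p.with_(sigma=0.01), cfg)
        assert np.array_equal(res.counts, st.counts(len(tr), tr.dt))

    def test_sum_mode_unsupported(self):
        p = ModelParams(probe="hill_rise", gamma=0.2, n_hill=2.0, tau_on=0.05,
                        sigma=0.02)
        tr = Trace(values=np.ones(10), dt=0.05)
        with pytest.raises(NotImplementedError):
            smoothed_spike_probabilities(tr, p)


class TestGridOptions:
    def test_rate_prior_flag(self):
        p = small_params(lam=0.5)
        tr = Trace(values=np.ones(20), dt=0.05)
        cfg = EngineConfig(nc=80, nb=1, B_known=1.0, c1_prior="rate")
        res = map_spikes(tr, p, cfg)
        assert res.counts.sum() == 0  # still no spikes on a flat trace

    def test_delay_shifts_estimates_back(self):
        p = small_params(sigma=0.02).with_(delay=0.04)
        st = SpikeTrain(times=np.array([1.0]))
        tr, _ = simulate_trace(st, p.with_(sigma=0.0), 2.0, 0.02, seed=0)
        res = map_spikes(tr, p.with_(sigma=0.005), FIXED_B)
        assert len(res.spikes) == 1
        assert res.spikes.times[0] == pytest.approx(1.0, abs=tr.dt)
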