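"""Spike matching, error rates, correlation and noise quantification."""

import itertools

import numpy as np
import pytest

from spikemap.metrics import (
    MatchResult,
    compute_A_prime,
    error_rate,
    match_spikes,
    mean_temporal_error,
    noise_level,
    photonic_gain,
    pooled_error_rate,
    rate_correlation,
)
from spikemap.model import ModelParams, SpikeTrain
from spikemap.synth import gen_poisson_train


def exhaustive_min_cost(a, b, tol):
    """Oracle: minimum alignment cost over all order-preserving matchings."""
    best = [np.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == len(a) and j == len(b):
            best[0] = cost
            return
        if i < len(a):
            rec(i + 1, j, cost + 1.0)
        if j < len(b):
            rec(i, j + 1, cost + 1.0)
        if i < len(a) and j < len(b) and abs(a[i] - b[j]) <= tol:
            rec(i + 1, j + 1, cost + abs(a[i] - b[j]) / tol)

    rec(0, 0, 0.0)
    return best[0]


def match_cost(m: MatchResult) -> float:
    shifts = sum(abs(t - e) / m.tolerance for t, e in m.pairs)
    return shifts + m.n_miss + m.n_false


class TestMatchSpikes:
    def test_within_tolerance_matched(self):
        m = match_spikes(SpikeTrain(times=[1.0]), SpikeTrain(times=[1.4]), 0.5)
        assert (m.n_match, m.n_miss, m.n_false) == (1, 0, 0)

    def test_beyond_tolerance_not_matched(self):
        m = match_spikes(SpikeTrain(times=[1.0]), SpikeTrain(times=[1.6]), 0.5)
        assert (m.n_match, m.n_miss, m.n_false) == (0, 1, 1)

    def test_doublet_against_single(self):
        m = match_spikes(SpikeTrain(times=[1.0, 1.1]), SpikeTrain(times=[1.05]), 0.5)
        assert (m.n_match, m.n_miss, m.n_false) == (1, 1, 0)
        oracle = exhaustive_min_cost([1.0, 1.1], [1.05], 0.5)
        assert match_cost(m) == pytest.approx(oracle)

    def test_matches_exhaustive_on_random_trains(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = np.sort(rng.uniform(0, 5, size=rng.integers(0, 7)))
            b = np.sort(rng.uniform(0, 5, size=rng.integers(0, 7)))
            m = match_spikes(SpikeTrain(times=a), SpikeTrain(times=b), 0.5)
            assert match_cost(m) == pytest.approx(
                exhaustive_min_cost(list(a), list(b), 0.5)
            )

    def test_pairs_within_tolerance(self):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 10, 20))
        b = np.sort(rng.uniform(0, 10, 25))
        m = match_spikes(SpikeTrain(times=a), SpikeTrain(times=b), 0.3)
        assert all(abs(t - e) <= 0.3 for t, e in m.pairs)
        assert m.n_match + m.n_miss == 20
        assert m.n_match + m.n_false == 25


class TestErrorRate:
    def test_perfect(self):
        m = match_spikes(SpikeTrain(times=[1, 2, 3]), SpikeTrain(times=[1, 2, 3]))
        assert error_rate(m)[2] == 0.0

    def test_formula(self):
        # sens=1, prec=0.5 -> ER = 1/3
        m = MatchResult(pairs=[(1.0, 1.0)], n_miss=0, n_false=1, tolerance=0.5)
        sens, prec, er = error_rate(m)
        assert (sens, prec) == (1.0, 0.5)
        assert er == pytest.approx(1 / 3)

    def test_nine_matched_one_missed(self):
        m = MatchResult(pairs=[(t, t) for t in range(9)], n_miss=1, n_false=0,
                        tolerance=0.5)
        assert error_rate(m)[2] == pytest.approx(1 - 18 / 19)

    def test_both_empty_flagged(self):
        m = match_spikes(SpikeTrain(times=[]), SpikeTrain(times=[]))
        with pytest.warns(UserWarning):
            assert error_rate(m)[2] == 0.0

    def test_symmetric_under_swap(self):
        a = SpikeTrain(times=[1.0, 2.0, 3.5])
        b = SpikeTrain(times=[1.1, 3.4, 4.8])
        assert error_rate(match_spikes(a, b))[2] == pytest.approx(
            error_rate(match_spikes(b, a))[2]
        )

    def test_biased_towards_worse_rate(self):
        """ER >= (miss rate + false rate)/2: harmonic <= arithmetic mean."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            nm = int(rng.integers(1, 20))
            miss = int(rng.integers(0, 10))
            false = int(rng.integers(0, 10))
            m = MatchResult(pairs=[(0.0, 0.0)] * nm, n_miss=miss, n_false=false,
                            tolerance=0.5)
            _, _, er = error_rate(m)
            miss_rate = miss / (nm + miss)
            false_rate = false / (nm + false)
            assert er >= (miss_rate + false_rate) / 2 - 1e-12

    def test_pooled_over_trials(self):
        trials = [
            MatchResult(pairs=[(0, 0)] * 5, n_miss=1, n_false=0, tolerance=0.5),
            MatchResult(pairs=[(0, 0)] * 3, n_miss=0, n_false=2, tolerance=0.5),
        ]
        sens, prec, er = pooled_error_rate(trials)
        assert sens == pytest.approx(8 / 9)
        assert prec == pytest.approx(8 / 10)


class TestTemporalError:
    def test_mean_absolute_delay(self):
        m = MatchResult(pairs=[(1.0, 1.01), (2.0, 1.97)], n_miss=0, n_false=0,
                        tolerance=0.5)
        assert mean_temporal_error(m) == pytest.approx(0.02)

    def test_no_pairs_undefined(self):
        m = MatchResult(pairs=[], n_miss=1, n_false=0, tolerance=0.5)
        with pytest.warns(UserWarning):
            assert np.isnan(mean_temporal_error(m))


class TestRateCorrelation:
    def test_identical_trains(self):
        # with no smoothing kernel the two binned vectors are identical;
        # the default 100 ms kernel (applied to the estimate only, per the
        # rate-reconstruction definition) lowers r even for a perfect train
        st = gen_poisson_train(2.0, 20.0, seed=0)
        assert rate_correlation(st, st, 20.0, kernel=0.0) == pytest.approx(1.0)
        assert rate_correlation(st, st, 20.0) > 0.4

    def test_empty_estimate_undefined(self):
        st = gen_poisson_train(2.0, 20.0, seed=1)
        with pytest.warns(UserWarning):
            assert np.isnan(rate_correlation(st, SpikeTrain(times=[]), 20.0))

    def test_shift_reduces_correlation(self):
        st = gen_poisson_train(3.0, 30.0, seed=2)
        shifted = SpikeTrain(times=np.clip(st.times + 0.04, 0, 29.999))
        r0 = rate_correlation(st, st, 30.0)
        r1 = rate_correlation(st, shifted, 30.0)
        assert r1 < r0

    def test_affine_invariance_of_rate_series(self):
        st = gen_poisson_train(2.0, 20.0, seed=3)
        series = np.histogram(st.times, bins=500, range=(0, 20))[0].astype(float)
        r1 = rate_correlation(st, series, 20.0)
        r2 = rate_correlation(st, 3.0 * series + 0.5, 20.0)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestNoiseLevel:
    def test_white_residual_formula(self):
        rng = np.random.default_rng(4)
        vals = [
            noise_level(0.02 * rng.standard_normal(2**14), np.zeros(2**14), 0.05, 0.01)
            for _ in range(20)
        ]
        assert np.mean(vals) == pytest.approx(0.02 * np.sqrt(5.8 / 100) / 0.05, rel=0.05)

    def test_zero_residual(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert noise_level(x, x, 0.05, 0.01) == 0.0

    def test_homogeneous(self):
        rng = np.random.default_rng(5)
        r = rng.standard_normal(4096)
        z = np.zeros(4096)
        assert noise_level(2 * r, z, 0.05, 0.01) == pytest.approx(
            2 * noise_level(r, z, 0.05, 0.01)
        )

    def test_invalid_a_prime(self):
        with pytest.raises(ValueError):
            noise_level(np.ones(10), np.ones(10), 0.0, 0.01)


class TestAPrime:
    def test_linear(self):
        assert compute_A_prime(ModelParams(A=0.1, probe="linear")) == pytest.approx(0.1)

    def test_saturating_below_A(self):
        p = ModelParams(A=0.1, probe="saturating", gamma=0.1)
        assert compute_A_prime(p) == pytest.approx(0.1 * (1.1 * 2 / 1.2) / 2)
        assert compute_A_prime(p) < p.A

    def test_gcamp6s_above_A(self):
        p = ModelParams(A=0.1, probe="polynomial", p2=0.73, p3=-0.05)
        assert compute_A_prime(p) == pytest.approx(0.1 * 3.16 / 2)
        assert compute_A_prime(p) > p.A

    def test_gcamp5k_uses_fifteen_spikes(self):
        p = ModelParams(A=0.1, probe="polynomial", p2=0.55, p3=0.03)
        from spikemap.model import nonlinearity

        assert compute_A_prime(p, "gcamp5k") == pytest.approx(
            0.1 * nonlinearity(15.0, p) / 15
        )


class TestPhotonicGain:
    def test_variance_recovery_factor(self):
        # ideal flat spectrum: Var_total = Var_hp * (fs/2)/((fs/2)-fc) = 5/3
        rng = np.random.default_rng(6)
        s = rng.standard_normal(2**16) + 10.0
        est = photonic_gain(s, 1000.0, 200.0)
        assert est == pytest.approx(1.0 / 10.0, rel=0.05)

    def test_poisson_photon_simulation(self):
        rng = np.random.default_rng(7)
        gain, N = 2.0, 100
        s = gain * rng.poisson(N, size=2**16)
        assert photonic_gain(s, 1000.0, 200.0) == pytest.approx(gain, rel=0.05)

    def test_zero_variance_input(self):
        assert photonic_gain(np.full(1000, 5.0), 1000.0, 200.0) == 0.0

    def test_band_limit_validation(self):
        with pytest.raises(ValueError):
            photonic_gain(np.ones(100), 300.0, 200.0)
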