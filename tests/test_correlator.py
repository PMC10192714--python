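"""Direct and multi-tau ACF estimators against hand-computable traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleodyn import IntensityTrace, direct_acf, multitau_acf, segment_acf
from nucleodyn.errors import DegenerateTraceError, InputError

BW = 2e-5  # 50 kHz


def poisson_trace(n, lam=10.0, seed=0):
    rng = np.random.default_rng(seed)
    return IntensityTrace(rng.poisson(lam, n), BW)


class TestDirect:
    def test_constant_trace_has_zero_correlation(self):
        g = direct_acf(IntensityTrace(np.full(1000, 5), BW), 10).g
        assert np.all(g == 0)

    def test_alternating_trace_hand_values(self):
        # x = 1,0,1,0,...: deltaF = +/-0.5 around mean 0.5, so G(1) = -1, G(2) = +1.
        trace = IntensityTrace(np.tile([1, 0], 500), BW)
        curve = direct_acf(trace, 4)
        assert curve.g[0] == pytest.approx(-1.0, abs=1e-12)
        assert curve.g[1] == pytest.approx(+1.0, abs=1e-12)

    def test_white_poisson_is_uncorrelated(self):
        n = 100_000
        curve = direct_acf(poisson_trace(n), 32)
        assert np.abs(curve.g).max() < 5 / np.sqrt(n)

    def test_zero_trace_raises(self):
        with pytest.raises(DegenerateTraceError):
            direct_acf(IntensityTrace(np.zeros(1000, dtype=int), BW), 10)

    def test_trace_must_exceed_twice_max_lag(self):
        with pytest.raises(InputError):
            direct_acf(IntensityTrace(np.ones(100, dtype=int), BW), 50)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(2, 1000))
    def test_scale_invariance(self, c):
        base = poisson_trace(5000, seed=3)
        scaled = IntensityTrace(base.counts * c, BW)
        g1 = direct_acf(base, 16).g
        g2 = direct_acf(scaled, 16).g
        assert np.allclose(g1, g2, atol=1e-12)


class TestMultiTau:
    def test_constant_trace_zero_everywhere(self):
        curve = multitau_acf(IntensityTrace(np.full(10_000, 7), BW))
        assert np.all(curve.g == 0)

    def test_first_octave_matches_direct(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5 + 3 * np.sin(np.arange(100_000) / 300.0))
        trace = IntensityTrace(counts, BW)
        d = direct_acf(trace, 16)
        m = multitau_acf(trace, 16)
        assert np.abs(m.g[:16] - d.g).max() < 1e-12

    def test_ladder_structure(self):
        curve = multitau_acf(poisson_trace(10_000), points_per_octave=16)
        bins = np.round(curve.lags / BW).astype(int)
        assert list(bins[:16]) == list(range(1, 17))
        assert list(bins[16:24]) == [18, 20, 22, 24, 26, 28, 30, 32]
        # spacing doubles again on the next level
        assert bins[24] - bins[23] == 4

    def test_odd_points_per_octave_rejected(self):
        with pytest.raises(InputError):
            multitau_acf(poisson_trace(10_000), points_per_octave=15)


class TestSegment:
    def test_identical_segments_have_zero_sem(self):
        seg = np.random.default_rng(0).poisson(8, 2000)
        trace = IntensityTrace(np.tile(seg, 10), BW)
        curve = segment_acf(trace, 10)
        assert np.all(curve.sem == 0)

    def test_independent_noise_has_positive_sem(self):
        curve = segment_acf(poisson_trace(50_000, seed=5), 10)
        assert np.all(curve.sem > 0)

    def test_sem_shrinks_with_square_root_of_segments(self):
        # fixed segment length, 4x as many segments -> sem halves
        seg_len = 25_000
        short = poisson_trace(4 * seg_len, seed=6)
        long = poisson_trace(16 * seg_len, seed=7)
        s4 = segment_acf(short, 4)
        s16 = segment_acf(long, 16)
        assert len(s4) == len(s16)  # same ladder at equal segment length
        ratio = np.median(s16.sem / s4.sem)
        assert 0.3 < ratio < 0.8  # ideal 1/2, allow estimator noise

    def test_segments_must_support_ladder(self):
        with pytest.raises(InputError):
            segment_acf(poisson_trace(200), 10)

    def test_requires_at_least_two_segments(self):
        with pytest.raises(InputError):
            segment_acf(poisson_trace(10_000), 1)


def test_concatenation_approaches_single_trace_acf():
    """Stationarity sanity: doubling a trace by self-concatenation barely moves G."""
    rng = np.random.default_rng(2)
    counts = rng.poisson(5 + 2 * np.sin(np.arange(50_000) / 100.0))
    single = IntensityTrace(counts, BW)
    double = IntensityTrace(np.concatenate([counts, counts]), BW)
    g1 = direct_acf(single, 16).g
    g2 = direct_acf(double, 16).g
    assert np.abs(g1 - g2).max() < 0.01
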