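"""Closed-form behaviour of the diffusion + two-binding ACF model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleodyn import ACFCurve, FCSParams, eval_acf_model, koff_from_residence
from nucleodyn.errors import InputError, ParameterError
from nucleodyn.model import GAMMA_3D


def make_params(n=1.0, fd=1.0, td=1e-3, om=5.0, fs=0.0, ts=0.01, fl=0.0, tl=1.0):
    return FCSParams(
        n_molecules=n, f_diff=fd, tau_diff=td, omega=om,
        f_short=fs, tau_short=ts, f_long=fl, tau_long=tl,
    )


@st.composite
def valid_params(draw):
    raw = [draw(st.floats(0.05, 1.0)) for _ in range(3)]
    total = sum(raw)
    fd, fs, fl = (r / total for r in raw)
    fl = 1.0 - fd - fs  # make the sum exact in floating point
    td = draw(st.floats(1e-5, 1e-2))
    ts = draw(st.floats(1e-3, 0.5))
    tl = ts * draw(st.floats(2.0, 100.0))
    n = draw(st.floats(0.1, 50.0))
    om = draw(st.floats(1.5, 20.0))
    return FCSParams(n_molecules=n, f_diff=fd, tau_diff=td, omega=om,
                     f_short=fs, tau_short=ts, f_long=fl, tau_long=tl)


class TestEvalModel:
    def test_pure_diffusion_zero_lag_is_gamma_over_n(self):
        p = make_params(n=1.0, fd=1.0)
        assert eval_acf_model(p, [0.0])[0] == pytest.approx(2 ** -1.5, abs=1e-15)

    def test_huge_lag_decays_to_zero(self):
        p = make_params(n=2, fd=0.5, fs=0.3, fl=0.2, ts=0.1, tl=2.0)
        tau = 1e9 * max(p.tau_diff, p.tau_long)
        assert eval_acf_model(p, [tau])[0] < 1e-6

    def test_term_by_term_hand_evaluation(self):
        # Independent oracle: each term computed separately with scalar math.
        p = make_params(n=2, fd=0.5, td=1e-3, om=5, fs=0.3, ts=0.1, fl=0.2, tl=2.0)
        tau = 1e-3
        diff = 0.5 / (2 ** 1.5 * 2) * (1 / (1 + tau / 1e-3)) * (1 + tau / (25 * 1e-3)) ** -0.5
        short = 0.3 * math.exp(-tau / 0.1)
        long_ = 0.2 * math.exp(-tau / 2.0)
        expected = diff + short + long_
        assert expected == pytest.approx(0.5402509279506802, rel=1e-12)
        assert eval_acf_model(p, [tau])[0] == pytest.approx(expected, rel=1e-12)

    def test_negative_or_nonfinite_lag_rejected(self):
        p = make_params()
        with pytest.raises(InputError):
            eval_acf_model(p, [-1e-3])
        with pytest.raises(InputError):
            eval_acf_model(p, [np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(valid_params())
    def test_zero_lag_closed_form(self, p):
        g0 = p.f_diff * GAMMA_3D / p.n_molecules + p.f_short + p.f_long
        assert eval_acf_model(p, [0.0])[0] == pytest.approx(g0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(valid_params())
    def test_strictly_decreasing(self, p):
        lags = np.logspace(-6, 2, 200)
        g = eval_acf_model(p, lags)
        assert np.all(np.diff(g) < 0)


class TestParamsInvariants:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ParameterError):
            make_params(fd=0.5, fs=0.3, fl=0.3)

    def test_time_ordering_enforced(self):
        with pytest.raises(ParameterError):
            make_params(fd=0.4, fs=0.3, fl=0.3, ts=2.0, tl=0.1)

    def test_omega_must_exceed_one(self):
        with pytest.raises(ParameterError):
            make_params(om=0.9)

    def test_population_fractions_are_amplitude_shares(self):
        p = make_params(n=2, fd=0.5, fs=0.3, fl=0.2, ts=0.1, tl=2.0)
        a = (0.5 * GAMMA_3D / 2, 0.3, 0.2)
        total = sum(a)
        assert p.population_fractions == pytest.approx(tuple(x / total for x in a))


class TestKoff:
    @pytest.mark.parametrize("tau,expected", [(0.5, 2.0), (1.0, 1.0), (2.0, 0.5)])
    def test_reciprocal(self, tau, expected):
        assert koff_from_residence(tau) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_domain_error(self, bad):
        with pytest.raises(ParameterError):
            koff_from_residence(bad)


class TestACFCurve:
    def test_requires_increasing_lags(self):
        with pytest.raises(InputError):
            ACFCurve(lags=np.array([1.0, 1.0, 2.0]), g=np.zeros(3))

    def test_rejects_negative_sem(self):
        with pytest.raises(InputError):
            ACFCurve(lags=np.array([1.0, 2.0]), g=np.zeros(2), sem=np.array([0.1, -0.1]))
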