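"""Tension-index, kinetics and fractional-shortening metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twitchlab.metrics import (compute_ti, fractional_shortening,
                               normalize_to_wt, trapz_integral,
                               twitch_kinetics)
from twitchlab.synth import SynthTwitchParams, synth_twitch
from twitchlab.trace import TwitchTrace


def make_trace(T, dt=1.0, **kw):
    T = np.asarray(T, dtype=float)
    return TwitchTrace(t=np.arange(T.size) * dt, T=T, **kw)


class TestNormalize:
    def test_self_normalization_peaks_at_100(self, wt_trace):
        n = normalize_to_wt(wt_trace, wt_trace)
        assert n.peak == pytest.approx(100.0, abs=1e-12)
        assert n.units == "%WT"

    def test_pointwise_half_gives_50(self, wt_trace):
        half = make_trace(wt_trace.T * 0.5, dt=wt_trace.dt)
        n = normalize_to_wt(half, wt_trace)
        assert n.peak == pytest.approx(50.0, rel=1e-12)

    def test_zero_wt_rejected(self):
        flat = make_trace(np.zeros(10))
        with pytest.raises(ValueError, match="non-positive maximum"):
            normalize_to_wt(flat, flat)

    def test_simulated_mutant_peak_is_half_wt(self, wt_trace, mutant_trace):
        n = normalize_to_wt(mutant_trace, wt_trace)
        assert n.peak == pytest.approx(50.0, abs=5.0)


class TestTrapz:
    def test_rectangle(self):
        assert trapz_integral(make_trace(np.ones(101))) == pytest.approx(100.0)

    def test_triangle(self):
        up = np.linspace(0, 100, 101)
        tri = make_trace(np.concatenate([up, up[::-1][1:]]))
        assert trapz_integral(tri) == pytest.approx(10_000.0)

    def test_matches_riemann_oracle_at_1khz(self, rng):
        """Trapezoid vs a 100x-finer midpoint-Riemann oracle, < 0.1%."""
        t = np.arange(0, 300.0, 1.0)
        smooth = np.abs(np.sum(
            [rng.normal() * np.sin(2 * np.pi * k * t / 300.0 + rng.normal())
             for k in range(1, 4)], axis=0)) + 1.0
        tr = make_trace(smooth)
        fine_t = np.linspace(t[0], t[-1], t.size * 100 + 1)
        mid = 0.5 * (fine_t[1:] + fine_t[:-1])
        riemann = float(np.sum(np.interp(mid, t, smooth) * np.diff(fine_t)))
        assert trapz_integral(tr) == pytest.approx(riemann, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trapz_integral(TwitchTrace(t=[0.0, 1.0], T=[1.0, 1.0]).resample([0.0]))


class TestTensionIndex:
    def test_wt_vs_itself_is_exactly_zero(self, wt_trace):
        assert compute_ti(wt_trace, wt_trace).value == 0.0

    def test_half_amplitude_gives_minus_half_wt_area(self, wt_trace):
        half = make_trace(wt_trace.T * 0.5, dt=wt_trace.dt)
        wt_pct = normalize_to_wt(wt_trace, wt_trace)
        expected = -0.5 * trapz_integral(wt_pct)
        assert compute_ti(half, wt_trace).value == pytest.approx(expected, rel=1e-12)

    def test_antisymmetry_against_common_reference(self, wt_trace, mutant_trace):
        a = normalize_to_wt(mutant_trace, wt_trace)
        b = normalize_to_wt(wt_trace, wt_trace)
        ti_ab = trapz_integral(a) - trapz_integral(b)
        ti_ba = trapz_integral(b) - trapz_integral(a)
        assert ti_ab == pytest.approx(-ti_ba, rel=1e-12)

    def test_invariant_to_common_unit_rescale(self, wt_trace, mutant_trace):
        ti = compute_ti(mutant_trace, wt_trace).value
        scaled_wt = make_trace(wt_trace.T * 7.3, dt=wt_trace.dt)
        scaled_mut = make_trace(mutant_trace.T * 7.3, dt=mutant_trace.dt)
        ti_scaled = compute_ti(scaled_mut, scaled_wt).value
        assert ti_scaled == pytest.approx(ti, rel=1e-9)

    def test_refinement_stability(self, wt_trace, mutant_trace):
        """TI at 1 kHz vs 10 kHz resampling differs by < 0.5%."""
        ti_1k = compute_ti(mutant_trace, wt_trace).value
        t10 = np.arange(wt_trace.t[0], wt_trace.t[-1] + 0.05, 0.1)
        wt10, mut10 = wt_trace.resample(t10), mutant_trace.resample(t10)
        ti_10k = compute_ti(mut10, wt10).value
        assert ti_10k == pytest.approx(ti_1k, rel=5e-3)


class TestKinetics:
    def test_triangular_pulse_geometry(self):
        up = np.linspace(0, 100, 101)
        tri = make_trace(np.concatenate([up, up[::-1][1:]]))
        k = twitch_kinetics(tri)
        assert k.time_to_peak == pytest.approx(100.0)
        assert k.RT50 == pytest.approx(50.0, abs=1e-9)
        assert k.RT90 == pytest.approx(90.0, abs=1e-9)
        assert k.RT50 <= k.RT90

    def test_exponential_twitch_matches_dense_oracle(self):
        """Metrics of A(1-e^(-t/20))e^(-t/60) vs a 100x-denser evaluation."""
        p = SynthTwitchParams(amplitude=100.0, tau_rise=20.0, tau_decay=60.0,
                              duration=400.0, dt=1.0)
        k = twitch_kinetics(synth_twitch(p))

        dense = synth_twitch(SynthTwitchParams(amplitude=100.0, tau_rise=20.0,
                                               tau_decay=60.0, duration=400.0,
                                               dt=0.01))
        kd = twitch_kinetics(dense)
        assert k.time_to_peak == pytest.approx(kd.time_to_peak, abs=1.0)
        assert k.RT50 == pytest.approx(kd.RT50, abs=1.0)
        assert k.RT90 == pytest.approx(kd.RT90, abs=1.0)

    def test_time_reversal_swaps_slope_magnitudes(self):
        up = np.linspace(0, 100, 51)
        down = np.linspace(100, 0, 151)
        pulse = make_trace(np.concatenate([up, down[1:]]))
        rev = make_trace(pulse.T[::-1])
        k, kr = twitch_kinetics(pulse), twitch_kinetics(rev)
        assert k.max_dTdt_up == pytest.approx(-kr.max_dTdt_down, rel=1e-9)
        assert k.max_dTdt_down == pytest.approx(-kr.max_dTdt_up, rel=1e-9)

    def test_monotone_trace_rejected(self):
        with pytest.raises(ValueError, match="interior maximum"):
            twitch_kinetics(make_trace(np.linspace(0, 1, 50)))


class TestFractionalShortening:
    @pytest.mark.parametrize("lvid_d, lvid_s, expected",
                             [(4.0, 3.0, 25.0), (4.0, 4.0, 0.0),
                              (4.0, 0.0, 100.0)])
    def test_formula(self, lvid_d, lvid_s, expected):
        assert fractional_shortening(lvid_d, lvid_s) == pytest.approx(expected)

    def test_paradoxical_motion_warns_but_returns(self):
        with pytest.warns(UserWarning, match="paradoxical"):
            fs = fractional_shortening(4.0, 4.4)
        assert fs == pytest.approx(-10.0)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            fractional_shortening(0.0, 0.0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(scale=st.floats(0.05, 3.0), amp=st.floats(1.0, 200.0))
def test_ti_sign_follows_area_ordering(scale, amp):
    """TI < 0 iff the variant's normalized area is below the reference's."""
    wt = synth_twitch(SynthTwitchParams(amplitude=100.0))
    var = synth_twitch(SynthTwitchParams(amplitude=amp,
                                         tau_decay=60.0 * scale))
    ti = compute_ti(var, wt).value
    a_var = trapz_integral(normalize_to_wt(var, wt))
    a_wt = trapz_integral(normalize_to_wt(wt, wt))
    assert np.sign(ti) == np.sign(a_var - a_wt)
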