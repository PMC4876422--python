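"""Constitutive-law unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epfem.model_core import (TissueState, capacitive_current_density,
                              conductivity, conductivity_and_slope,
                              target_poration, update_damage, update_poration)
from epfem.params import TissueParameters

P = TissueParameters()


class TestTargetPoration:
    @pytest.mark.parametrize("emag, expected", [
        (0.0, 0.0),
        (20_000.0, 0.0),          # lower ramp limit maps inclusively to 0
        (30_000.0, 0.5),          # midpoint of the linear ramp
        (40_000.0, 1.0),          # upper ramp limit maps inclusively to 1
        (80_000.0, 1.0),
    ])
    def test_linear_ramp(self, emag, expected):
        assert target_poration(emag, P) == pytest.approx(expected, abs=1e-15)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            target_poration(-1.0, P)

    def test_monotone_and_continuous(self):
        e = np.linspace(0, 60_000, 4001)
        t = target_poration(e, P)
        assert np.all(np.diff(t) >= 0)
        assert np.max(np.abs(np.diff(t))) < 2e-3   # no jumps on a fine grid


class TestUpdatePoration:
    def test_virgin_zero_field_fixed_point(self):
        assert update_poration(0.0, 0.0, 1.0, P) == 0.0

    def test_relaxation_one_time_constant(self):
        # p falls from 1 toward 0 with tau_relax = 100 us
        p1 = update_poration(1.0, 0.0, 100e-6, P)
        assert p1 == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_fast_rise_to_target(self):
        assert update_poration(0.2, 50_000.0, 2e-6, P) == 1.0

    def test_invalid_previous_level(self):
        with pytest.raises(ValueError):
            update_poration(1.2, 0.0, 1e-6, P)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.floats(0, 1e5), st.floats(1e-7, 1e-2)),
                    min_size=1, max_size=40))
    def test_stays_in_unit_interval(self, seq):
        p = 0.0
        for emag, dt in seq:
            p = update_poration(p, emag, dt, P)
            assert 0.0 <= p <= 1.0


class TestUpdateDamage:
    def test_zero_field_adds_nothing_during_pulse(self):
        assert update_damage(0.7, 0.0, 1e-4, True, P.alphaP, P.tauRelax) == 0.7

    def test_growth_arithmetic(self):
        # alpha * E * dt with the fitted poration-damage amplitude
        d = update_damage(0.0, 50_000.0, 100e-6, True, 0.0015, P.tauRelax)
        assert d == pytest.approx(0.0075, rel=1e-12)

    def test_decay_one_time_constant(self):
        d = update_damage(2.0, 0.0, 5e-3, False, P.alphaP, 5e-3)
        assert d == pytest.approx(2.0 * np.exp(-1.0), rel=1e-12)

    def test_negative_damage_rejected(self):
        with pytest.raises(ValueError):
            update_damage(-0.1, 0.0, 1e-6, True, P.alphaP, P.tauRelax)

    def test_strictly_decreasing_between_pulses(self):
        d = 1.0
        for _ in range(5):
            d_new = update_damage(d, 0.0, 1e-4, False, P.alphaP, P.tauRelax)
            assert d_new < d
            d = d_new


class TestConductivity:
    def test_virgin_baseline(self):
        assert conductivity(0.0, 0.0, 0.0, P) == pytest.approx(0.065, rel=1e-12)

    def test_fully_porated_undamaged(self):
        assert conductivity(1.0, 0.0, 0.0, P) == pytest.approx(0.1483, rel=1e-12)

    def test_saturated_ceiling(self):
        # sigmaMax * (1 + Apg) * (1 + AT)
        sig = conductivity(1.0, 1e6, 1e6, P)
        assert sig == pytest.approx(0.1483 * 1.35 * 1.125, rel=1e-6)
        assert sig == pytest.approx(0.22523, abs=5e-6)

    def test_monotone_in_each_argument(self, rng):
        pts = rng.uniform(0, 1, size=(50, 3)) * np.array([1.0, 1e-4, 1.0])
        for p, dp, dt in pts:
            base = conductivity(p, dp, dt, P)
            assert conductivity(min(p + 0.01, 1), dp, dt, P) >= base
            assert conductivity(p, dp + 1e-6, dt, P) >= base
            assert conductivity(p, dp, dt + 1e-2, P) >= base

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1e3), st.floats(0, 1e3))
    def test_bounded(self, p, dp, dt):
        sig = conductivity(p, dp, dt, P)
        assert P.sigma0 * (1 - 1e-12) <= sig <= P.sigma_ceiling() * (1 + 1e-12)

    def test_field_slope_matches_finite_difference(self):
        for emag in (25_000.0, 35_000.0):
            _, slope = conductivity_and_slope(0.0, 0.0, 0.0, emag, 1e-5, P)
            de = 1.0
            s_hi, _ = conductivity_and_slope(0.0, 0.0, 0.0, emag + de, 1e-5, P)
            s_lo, _ = conductivity_and_slope(0.0, 0.0, 0.0, emag - de, 1e-5, P)
            assert slope == pytest.approx((s_hi - s_lo) / (2 * de), rel=1e-6)


class TestCapacitiveCurrent:
    def test_steady_state_no_current(self):
        j, mem = capacitive_current_density(300.0, 300.0, 1e-6,
                                            np.array([0, 0, 1.0]), P)
        assert np.allclose(j, 0.0)
        assert mem == pytest.approx(300.0)

    def test_step_spike_amplitude(self):
        # a 500 V step launches a spike of A_C * dU / R = 0.0167 A/m^2
        dt = 1e-9   # << RC so the decay factor is ~1
        j, _ = capacitive_current_density(500.0, 0.0, dt, np.array([0, 0, 1.0]), P)
        assert np.linalg.norm(j) == pytest.approx(P.AC * 500.0 / P.R, rel=1e-3)
        assert np.linalg.norm(j) == pytest.approx(0.0167, rel=1e-2)

    def test_discharge_sign_opposes_field_direction(self):
        # after the pulse falls, uLocal < memory: current reverses
        j, _ = capacitive_current_density(0.0, 400.0, 1e-6, np.array([0, 0, 1.0]), P)
        assert j[2] < 0

    def test_rc_time_constant(self):
        assert P.rc_time == pytest.approx(1.8e-6, rel=1e-12)

    def test_step_response_decay_rate(self):
        """Log-magnitude of the spike decays with slope -1/(RC) within 1%."""
        dt = 2e-8
        mem = 0.0
        mags, times = [], []
        t = 0.0
        for k in range(400):
            j, mem = capacitive_current_density(500.0, mem, dt,
                                                np.array([0, 0, 1.0]), P)
            t += dt
            times.append(t)
            mags.append(np.linalg.norm(j))
        sel = np.array(mags) > 1e-12
        slope = np.polyfit(np.array(times)[sel], np.log(np.array(mags)[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / P.rc_time, rel=0.01)


class TestRelaxation:
    def test_returns_to_virgin_after_long_rest(self):
        """After rest >= 10*max(tau) the state relaxes to sigma0 within 1e-3."""
        state = TissueState.virgin(1, P)
        from epfem.model_core import advance_state
        E = np.array([[0.0, 0.0, 50_000.0]])
        t = 0.0
        for _ in range(50):                      # one 100 us pulse at 50 kV/m
            t += 2e-6
            state = advance_state(state, E, np.array([250.0]), 2e-6, True, P, t)
        assert state.p[0] == 1.0
        assert state.sigma[0] > 0.2              # near the ceiling
        rest = 10 * max(P.tauRelax, P.tauPg, P.tauT)
        zero = np.zeros((1, 3))
        for _ in range(10):                      # rest in 10 equal chunks
            t += rest / 10
            state = advance_state(state, zero, np.array([0.0]), rest / 10,
                                  False, P, t)
        assert state.p[0] < 1e-3
        assert state.sigma[0] == pytest.approx(P.sigma0, rel=1e-3)
        assert state.dP[0] < 1e-6


def test_virgin_state_validates():
    st_ = TissueState.virgin(10, P)
    st_.validate(P)
    assert np.all(st_.sigma == P.sigma0)
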