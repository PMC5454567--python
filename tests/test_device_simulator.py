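import math
from dataclasses import replace
from datetime import time as dtime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from legdose import (BreakModel, HRParams, ParticipantModel, ProtocolSpec,
                     ScheduledSession, ThermalParams, dosed_week_schedule,
                     hr_controller, simulate_cohort, simulate_hr,
                     simulate_protocol, simulate_thermal, simulate_week)
from legdose.device_simulator import OPPORTUNISTIC_POWER
from legdose.errors import (ConfigurationError, SchedulingError,
                            ValidationError)
from tests.conftest import START, WEEK_START


def closed_form(k, lam, p, t, amb=0.0):
    """Independent oracle: analytic solution of dT/dt = kP - lam(T-amb)."""
    if lam == 0:
        return k * p * t
    return (amb + k * p / lam) * (1.0 - math.exp(-lam * t))


class TestSimulateThermal:
    def test_zero_power_stays_zero(self):
        params = ThermalParams(ambient_offset=0.0)
        assert np.all(simulate_thermal(np.zeros(60), params) == 0.0)

    def test_constant_power_matches_closed_form(self):
        # k=0.01, lam=0.05, P=100 W, 30 min -> about 15.54 degC
        params = ThermalParams(heat_coefficient=0.01, cooling_rate=0.05)
        out = simulate_thermal(np.full(30, 100.0), params)
        expected = closed_form(0.01, 0.05, 100.0, 30)
        assert expected == pytest.approx(15.537, abs=5e-3)
        assert out[-1] == pytest.approx(expected, rel=1e-9)

    def test_closed_form_grid(self):
        for k in (0.004, 0.0072, 0.01):
            for lam in (0.01, 0.05, 0.1, 0.2):
                for p in (20.0, 70.0, 150.0):
                    params = ThermalParams(heat_coefficient=k, cooling_rate=lam)
                    out = simulate_thermal(np.full(40, p), params)
                    for t in (1, 5, 20, 40):
                        assert out[t - 1] == pytest.approx(
                            closed_form(k, lam, p, t), rel=0.01)

    def test_monotone_in_power(self, rng):
        params = ThermalParams()
        p2 = rng.uniform(0, 100, 50)
        p1 = p2 + rng.uniform(0, 50, 50)
        t1 = simulate_thermal(p1, params)
        t2 = simulate_thermal(p2, params)
        assert np.all(t1 >= t2 - 1e-12)

    def test_pure_integrator_when_cooling_off(self, rng):
        params = ThermalParams(cooling_rate=0.0)
        p = rng.uniform(0, 120, 30)
        out = simulate_thermal(p, params)
        np.testing.assert_allclose(out, params.heat_coefficient * np.cumsum(p),
                                   rtol=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            ThermalParams(heat_coefficient=0.0)
        with pytest.raises(ValidationError):
            ThermalParams(cooling_rate=-0.1)
        with pytest.raises(ValidationError):
            simulate_thermal(np.array([-1.0]), ThermalParams())
        with pytest.raises(ValidationError):
            simulate_thermal(np.array([]), ThermalParams())

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.001, max_value=0.02),
           st.floats(min_value=0.001, max_value=0.2),
           st.floats(min_value=0.0, max_value=300.0),
           st.integers(min_value=1, max_value=90))
    def test_closed_form_property(self, k, lam, p, n):
        params = ThermalParams(heat_coefficient=k, cooling_rate=lam)
        out = simulate_thermal(np.full(n, p), params)
        assert out[-1] == pytest.approx(closed_form(k, lam, p, n), rel=0.01, abs=1e-9)


class TestSimulateHR:
    def test_rest_fixed_point(self):
        params = HRParams(hr_noise_sd=0.0)
        hr = simulate_hr(np.zeros(30), params)
        assert np.allclose(hr, params.hr_rest)

    def test_step_response_geometric_limit(self):
        params = HRParams(hr_rest=65, hr_gain=0.5, tau=2.0, hr_noise_sd=0.0)
        p = 80.0
        hr = simulate_hr(np.full(60, p), params)
        target = params.hr_rest + params.hr_gain * p
        assert np.all(np.diff(hr) >= -1e-12)  # monotone approach
        after_5tau = int(5 * params.tau)
        assert hr[after_5tau:] == pytest.approx(target, rel=0.01)
        # independent oracle: geometric-series solution of the recursion
        alpha = 1 - math.exp(-1 / params.tau)
        expected = target + (params.hr_rest - target) * (1 - alpha) ** 10
        assert hr[9] == pytest.approx(expected, rel=1e-9)

    def test_seed_determinism(self):
        params = HRParams()
        p = np.full(30, 50.0)
        assert np.array_equal(simulate_hr(p, params, rng=42),
                              simulate_hr(p, params, rng=42))

    def test_clipping(self):
        params = HRParams(hr_rest=95, hr_gain=2.0, tau=1.0, hr_noise_sd=0.0)
        hr = simulate_hr(np.full(30, 500.0), params)
        assert hr.max() <= 220.0


class TestHRController:
    def test_band_100_10_default_participant(self, participant):
        p = hr_controller((100, 10), participant, 40)
        hr = simulate_hr(p, replace(participant.hr, hr_noise_sd=0.0))
        assert np.all((hr[10:] >= 90) & (hr[10:] <= 110))

    def test_higher_band_higher_power(self, participant):
        p100 = hr_controller((100, 10), participant, 30)
        p120 = hr_controller((120, 10), participant, 30)
        assert p120.mean() > p100.mean()

    def test_band_at_rest_power_zero(self, participant):
        p = hr_controller((participant.hr.hr_rest, 10), participant, 30)
        assert p[-1] == pytest.approx(0.0, abs=1e-6)

    def test_unachievable_band(self, participant):
        with pytest.raises(ConfigurationError):
            hr_controller((participant.hr.hr_rest - 20, 10), participant, 30)
        with pytest.raises(ConfigurationError):
            hr_controller((230, 10), participant, 30)


class TestProtocolSpec:
    def test_dosed_mict_fixed(self):
        spec = ProtocolSpec(kind="dosed_mict")
        assert spec.duration == 30 and spec.target_hr_band == (100.0, 10.0)
        with pytest.raises(ConfigurationError):
            ProtocolSpec(kind="dosed_mict", duration=45)

    def test_hiit_fixed_25(self):
        assert ProtocolSpec(kind="hiit_wingate").duration == 25

    def test_mict_duration_bounds(self):
        ProtocolSpec(kind="mict", duration=10)
        ProtocolSpec(kind="mict", duration=120)
        for bad in (None, 9, 121):
            with pytest.raises(ConfigurationError):
                ProtocolSpec(kind="mict", duration=bad)

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            ProtocolSpec(kind="swimming")


class TestSimulateProtocol:
    def test_hiit_structure(self, participant):
        spec = ProtocolSpec(kind="hiit_wingate", seed=3)
        sim = simulate_protocol(spec, participant, START, noise_scale=0.0)
        p = sim.activity.power
        assert p.size == 25
        mixed = 0.5 * (spec.high_power + spec.moderate_power)
        high_minutes = np.flatnonzero(p == mixed)
        assert high_minutes.size == 10  # one averaged sample per 30-s burst
        assert np.all(np.diff(high_minutes) >= 2)  # separated by moderate blocks
        assert np.all(p[p != mixed] == spec.moderate_power)
        # telemetry: zeroing sample + 25 session rows
        assert len(sim.series) == 26
        assert sim.series.frame["temperature_c"].iloc[0] == 0.0

    def test_dosed_mict_calibrated_k_hits_target_dose(self):
        # choose k so that the closed-form 30-min dose is exactly 10.5 degC
        band_power = (100.0 - 65.0) / 0.5
        lam = 0.05
        k = 10.5 * lam / (band_power * (1 - math.exp(-lam * 30)))
        participant = ParticipantModel(
            thermal=ThermalParams(heat_coefficient=k, cooling_rate=lam))
        sim = simulate_protocol(ProtocolSpec(kind="dosed_mict"), participant,
                                START, noise_scale=0.0)
        dt30 = sim.series.frame["temperature_c"].iloc[30]
        assert dt30 == pytest.approx(10.5, rel=0.02)

    def test_bed_without_breaks_fully_active(self, participant):
        spec = ProtocolSpec(kind="bed_opportunistic", duration=120,
                            break_model=BreakModel(enabled=False))
        sim = simulate_protocol(spec, participant, START)
        assert sim.activity.active_minutes == 120

    def test_determinism(self, participant):
        spec = ProtocolSpec(kind="desk_opportunistic", seed=7)
        a = simulate_protocol(spec, participant, START)
        b = simulate_protocol(spec, participant, START)
        assert a.series == b.series
        assert np.array_equal(a.activity.power, b.activity.power)

    def test_opportunistic_has_no_hr(self, participant):
        sim = simulate_protocol(ProtocolSpec(kind="bed_opportunistic", seed=1),
                                participant, START)
        assert sim.series.frame["heart_rate_bpm"].isna().all()

    def test_truncation(self, participant):
        spec = ProtocolSpec(kind="mict", duration=35, truncate_minutes=15)
        sim = simulate_protocol(spec, participant, START)
        assert len(sim.series) == 16
        assert sim.activity.power.size == 15


class TestSimulateWeek:
    def test_dosed_week_five_sessions_reach_dose(self, participant):
        week = simulate_week(dosed_week_schedule([1, 3, 4, 5, 7]),
                             participant, WEEK_START, seed=2)
        assert len(week.boundaries) == 5
        dose = participant.thermal.constant_power_rise(
            (100.0 - participant.hr.hr_rest) / participant.hr.hr_gain, 30)
        for b in week.boundaries:
            window = week.series.frame.loc[b.start:b.end, "temperature_c"]
            assert (window - b.zero_reference).max() >= dose

    def test_empty_schedule_ambient_only(self, participant):
        week = simulate_week([], participant, WEEK_START, seed=0,
                             noise_scale=0.0, ambient_absolute=22.0)
        assert week.boundaries == [] and week.activities == []
        assert len(week.series) == 7 * 1440 + 1
        np.testing.assert_allclose(
            week.series.frame["temperature_c"].to_numpy(), 22.0, atol=1e-9)

    def test_truncated_session_below_30min_dose(self, participant):
        sched = [ScheduledSession(day=2, spec=ProtocolSpec(
            kind="mict", duration=35, truncate_minutes=15))]
        week = simulate_week(sched, participant, WEEK_START, seed=5)
        b = week.boundaries[0]
        peak = (week.series.frame.loc[b.start:b.end, "temperature_c"]
                - b.zero_reference).max()
        band_power = (100.0 - participant.hr.hr_rest) / participant.hr.hr_gain
        dose30 = participant.thermal.constant_power_rise(band_power, 30)
        assert peak < dose30  # closed form: rise(15) < rise(30)

    def test_overlap_rejected(self, participant):
        sched = [
            ScheduledSession(day=1, spec=ProtocolSpec(kind="dosed_mict"),
                             start_time=dtime(9, 0)),
            ScheduledSession(day=1, spec=ProtocolSpec(kind="dosed_mict"),
                             start_time=dtime(9, 20)),
        ]
        with pytest.raises(SchedulingError):
            simulate_week(sched, participant, WEEK_START)

    def test_sessions_zeroed_at_own_reference(self, participant):
        week = simulate_week(dosed_week_schedule([2, 6]), participant,
                             WEEK_START, seed=8)
        for b in week.boundaries:
            first = week.series.frame.loc[b.start, "temperature_c"]
            assert first == pytest.approx(b.zero_reference)

    def test_determinism(self, participant):
        a = simulate_week(dosed_week_schedule([1, 4]), participant, WEEK_START, seed=3)
        b = simulate_week(dosed_week_schedule([1, 4]), participant, WEEK_START, seed=3)
        assert a.series == b.series


class TestSimulateCohort:
    def test_point_ranges_fully_determined(self):
        het = {"heat_coefficient": (0.008, 0.008), "hr_rest": (70.0, 70.0)}
        cohort = simulate_cohort(1, het, seed=0)
        assert cohort[0].thermal.heat_coefficient == 0.008
        assert cohort[0].hr.hr_rest == 70.0

    def test_seed_determinism(self):
        assert simulate_cohort(5, seed=9) == simulate_cohort(5, seed=9)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(2, {"heat_coefficient": (0.01, 0.005)})

    def test_default_k_range_spans_dose_range(self, participant):
        # closed-form map from k to the 30-min dose at the 100+/-10 band
        cohort = simulate_cohort(7, seed=4)
        for model in cohort:
            band_power = (100.0 - model.hr.hr_rest) / model.hr.hr_gain
            dose = model.thermal.constant_power_rise(band_power, 30)
            assert 4.5 - 0.1 <= dose <= 10.5 + 0.1

    def test_simulated_doses_in_range(self):
        cohort = simulate_cohort(7, seed=4)
        for model in cohort:
            sim = simulate_protocol(ProtocolSpec(kind="dosed_mict", seed=1),
                                    model, START)
            dt30 = sim.series.frame["temperature_c"].iloc[30]
            assert 4.5 - 0.3 <= dt30 <= 10.5 + 0.3
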