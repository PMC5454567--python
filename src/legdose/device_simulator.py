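"""Synthetic telemetry generator for the instrumented leg-training device.

The device is modelled as a linear first-order thermal system: mechanical
work heats the resistance unit and Newtonian cooling relaxes it toward
ambient,

    dT/dt = k * P(t) - lambda * (T - ambient_offset),    T(0) = 0,

with ``k`` in degC per watt-minute and ``lambda`` per minute.  At constant
power the rise follows the closed form ``(k*P/lambda) * (1 - exp(-lambda*t))``
(plus the ambient term); the discrete propagation below is the exact
solution of the ODE over each one-minute step, so it matches that closed
form to machine precision at integer minutes.

Heart rate follows a first-order response toward ``hr_rest + hr_gain * P``
with time constant ``tau`` and optional Gaussian per-minute noise.  SpO2 is
a steady baseline with small noise; systolic blood pressure drifts linearly
with accumulated active minutes (placeholder dynamics only).

Five session protocols are supported: free-duration moderate continuous
training (``mict``), the fixed 30-minute dosed variant at 100+/-10 BPM
(``dosed_mict``), a 10-cycle high/moderate interval protocol
(``hiit_wingate``, 25 minutes), and two opportunistic kinds with
geometric active/break block alternation (``desk_opportunistic``,
``bed_opportunistic``).

All randomness flows from one seeded generator per ``simulate_*`` call, so
every simulation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import time as dtime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, SchedulingError, ValidationError
from .telemetry_io import SessionBoundary, TelemetrySeries

HR_CLIP = (40.0, 220.0)

#: Default measurement-noise scales (multiplied by ``noise_scale``).
TEMP_NOISE_SD = 0.05   # degC per sample
SPO2_NOISE_SD = 0.5    # percentage points

PROTOCOL_KINDS = ("mict", "dosed_mict", "hiit_wingate",
                  "desk_opportunistic", "bed_opportunistic")

#: Nominal per-block power ranges (W) for the opportunistic kinds.
OPPORTUNISTIC_POWER = {
    "desk_opportunistic": (55.0, 95.0),
    "bed_opportunistic": (45.0, 80.0),
}


@dataclass(frozen=True)
class ThermalParams:
    """Thermal response of the resistance unit.

    ``cooling_rate`` may be zero (adiabatic limit: pure work integrator);
    negative rates are rejected.
    """

    heat_coefficient: float = 0.0072   # degC per W*min
    cooling_rate: float = 0.05         # 1/min
    ambient_offset: float = 0.0        # degC relative to session zero

    def __post_init__(self):
        if self.heat_coefficient <= 0:
            raise ValidationError("heat_coefficient must be > 0")
        if self.cooling_rate < 0:
            raise ValidationError("cooling_rate must be >= 0")

    def constant_power_rise(self, power: float, minutes: float) -> float:
        """Closed-form session-relative rise after ``minutes`` at constant power."""
        lam = self.cooling_rate
        if lam == 0:
            return self.heat_coefficient * power * minutes
        steady = self.ambient_offset + self.heat_coefficient * power / lam
        return steady * (1.0 - math.exp(-lam * minutes))


@dataclass(frozen=True)
class HRParams:
    """First-order heart-rate response parameters."""

    hr_rest: float = 65.0      # BPM
    hr_gain: float = 0.5       # BPM per W
    tau: float = 2.0           # minutes
    hr_noise_sd: float = 2.0   # BPM

    def __post_init__(self):
        if not 40.0 <= self.hr_rest <= 100.0:
            raise ValidationError("hr_rest must lie in [40, 100] BPM")
        if self.hr_gain <= 0:
            raise ValidationError("hr_gain must be > 0")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.hr_noise_sd < 0:
            raise ValidationError("hr_noise_sd must be >= 0")


@dataclass(frozen=True)
class ParticipantModel:
    """Per-participant device and physiology parameters."""

    participant_id: str = "default"
    thermal: ThermalParams = field(default_factory=ThermalParams)
    hr: HRParams = field(default_factory=HRParams)
    spo2_baseline: float = 98.0
    systolic_baseline: float = 120.0
    diastolic_baseline: float = 80.0
    bp_exercise_slope: float = 2.0   # mmHg systolic per 10 active minutes

    def __post_init__(self):
        if not 50.0 < self.spo2_baseline <= 100.0:
            raise ValidationError("spo2_baseline must lie in (50, 100]")


@dataclass(frozen=True)
class BreakModel:
    """Geometric active/break block alternation for opportunistic sessions.

    Block lengths are geometric with the given means (active blocks are at
    least one minute, breaks at least three).  Defaults give ~68% duty,
    i.e. roughly 75 active minutes in a default 110-minute opportunistic
    session.
    """

    mean_active_minutes: float = 15.0
    mean_break_minutes: float = 7.0
    enabled: bool = True

    def __post_init__(self):
        if self.mean_active_minutes < 1 or self.mean_break_minutes < 1:
            raise ValidationError("break-model block means must be >= 1 minute")


@dataclass(frozen=True)
class ProtocolSpec:
    """One training-session specification.

    ``duration`` is fixed by the protocol for ``dosed_mict`` (30 min) and
    ``hiit_wingate`` (10 cycles of 0.5 + 2 min = 25 min); ``mict`` requires
    an explicit duration in [10, 120] min; opportunistic kinds default to
    110 min.  ``truncate_minutes`` cuts the session short (an abandoned
    bout) without changing the protocol definition.
    """

    kind: str
    duration: Optional[int] = None
    target_hr_band: tuple[float, float] = (100.0, 10.0)
    high_power: float = 250.0
    moderate_power: float = 100.0
    break_model: BreakModel = field(default_factory=BreakModel)
    seed: int = 0
    truncate_minutes: Optional[int] = None

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ConfigurationError(
                f"unknown protocol kind {self.kind!r}; expected one of {PROTOCOL_KINDS}")
        duration = self.duration
        if self.kind == "dosed_mict":
            if duration not in (None, 30):
                raise ConfigurationError("dosed_mict duration is fixed at 30 minutes")
            duration = 30
            object.__setattr__(self, "target_hr_band", (100.0, 10.0))
        elif self.kind == "hiit_wingate":
            if duration not in (None, 25):
                raise ConfigurationError("hiit_wingate duration is fixed at 25 minutes")
            duration = 25
            if self.high_power <= self.moderate_power:
                raise ConfigurationError("hiit_wingate requires high_power > moderate_power")
        elif self.kind == "mict":
            if duration is None:
                raise ConfigurationError("mict requires an explicit duration")
            if not 10 <= duration <= 120:
                raise ConfigurationError("mict duration must lie in [10, 120] minutes")
        else:  # opportunistic
            duration = 110 if duration is None else duration
            if duration < 1:
                raise ConfigurationError("duration must be >= 1 minute")
        object.__setattr__(self, "duration", int(duration))
        if self.truncate_minutes is not None:
            if not 1 <= self.truncate_minutes <= self.duration:
                raise ConfigurationError("truncate_minutes must lie in [1, duration]")

    @property
    def effective_duration(self) -> int:
        """Active minutes actually simulated (after truncation)."""
        if self.truncate_minutes is not None:
            return int(self.truncate_minutes)
        return int(self.duration)


@dataclass(frozen=True)
class ActivityTrace:
    """Ground-truth per-minute activity for one simulated session."""

    session_id: str
    kind: str
    timestamps: pd.DatetimeIndex
    power: np.ndarray          # W applied during [t, t+1)
    active: np.ndarray         # bool, power > 0

    @property
    def active_minutes(self) -> int:
        return int(np.count_nonzero(self.active))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.timestamps, "power_w": self.power,
            "active": self.active.astype(int),
            "kind": self.kind, "session_id": self.session_id})


@dataclass(frozen=True)
class SimulatedSession:
    series: TelemetrySeries
    boundary: SessionBoundary
    activity: ActivityTrace


@dataclass(frozen=True)
class ScheduledSession:
    """One entry of a week schedule: protocol on day 1..7 at a start time."""

    day: int
    spec: ProtocolSpec
    start_time: dtime = dtime(9, 0)

    def __post_init__(self):
        if not 1 <= self.day <= 7:
            raise SchedulingError(f"day must lie in 1..7, got {self.day}")


@dataclass(frozen=True)
class SimulatedWeek:
    """Continuous 7-day absolute-temperature trace plus per-session truth."""

    series: TelemetrySeries
    boundaries: list[SessionBoundary]
    activities: list[ActivityTrace]


# ---------------------------------------------------------------------------
# core dynamics


def simulate_thermal(power: Sequence[float], params: ThermalParams) -> np.ndarray:
    """Propagate device temperature through one-minute power steps.

    ``power[i]`` is the constant power applied during minute ``i``;
    the returned array gives the session-relative temperature at the END
    of each minute (exact ODE solution per step), same length as ``power``.
    """
    p = np.asarray(power, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("power series must be a nonempty 1-D array")
    if (p < 0).any():
        raise ValidationError("power must be >= 0")
    k, lam, amb = params.heat_coefficient, params.cooling_rate, params.ambient_offset
    if lam == 0:
        return k * np.cumsum(p)
    a = math.exp(-lam)
    drive = (k * p / lam + amb) * (1.0 - a)
    return lfilter([1.0], [1.0, -a], drive)


def simulate_hr(power: Sequence[float], params: HRParams,
                rng=None, hr0: Optional[float] = None) -> np.ndarray:
    """First-order heart-rate response to a per-minute power series.

    Returns HR at the end of each minute, starting from ``hr0``
    (resting HR by default), clipped to physiological bounds.
    Deterministic for a fixed generator/seed.
    """
    p = np.asarray(power, dtype=float)
    if (p < 0).any():
        raise ValidationError("power must be >= 0")
    rng = np.random.default_rng(rng)
    alpha = 1.0 - math.exp(-1.0 / params.tau)
    noise = (rng.normal(0.0, params.hr_noise_sd, p.size)
             if params.hr_noise_sd > 0 else np.zeros(p.size))
    hr = params.hr_rest if hr0 is None else float(hr0)
    out = np.empty(p.size)
    for i in range(p.size):
        target = params.hr_rest + params.hr_gain * p[i]
        hr = hr + (target - hr) * alpha + noise[i]
        hr = min(max(hr, HR_CLIP[0]), HR_CLIP[1])
        out[i] = hr
    return out


def hr_controller(target_band: tuple[float, float],
                  participant: ParticipantModel, duration: int) -> np.ndarray:
    """Per-minute power series a self-pacing user would apply to hold HR
    inside ``target_band`` (center, half-width).

    Feed-forward steady-state power plus proportional correction against
    the noise-free HR model; converges well inside a 10-minute burn-in.
    """
    center, half = float(target_band[0]), float(target_band[1])
    hrp = participant.hr
    if center < hrp.hr_rest:
        raise ConfigurationError(
            f"band center {center} BPM below resting HR {hrp.hr_rest}")
    if center >= HR_CLIP[1]:
        raise ConfigurationError(f"band center {center} BPM unachievable")
    if half <= 0:
        raise ConfigurationError("band half-width must be > 0")
    alpha = 1.0 - math.exp(-1.0 / hrp.tau)
    p_ff = max(0.0, (center - hrp.hr_rest) / hrp.hr_gain)
    kp = 0.8 / hrp.hr_gain
    hr = hrp.hr_rest
    out = np.empty(int(duration))
    for t in range(int(duration)):
        p = max(0.0, p_ff + kp * (center - hr))
        out[t] = p
        hr = hr + (hrp.hr_rest + hrp.hr_gain * p - hr) * alpha
    return out


# ---------------------------------------------------------------------------
# protocol power construction


def _hiit_power(spec: ProtocolSpec) -> np.ndarray:
    # 10 cycles of 30 s high + 2 min moderate on a 1-min grid: each high
    # block starts at 2.5*c minutes and never crosses a minute boundary,
    # so minute floor(2.5*c) carries the averaged 0.5*high + 0.5*moderate.
    p = np.full(25, spec.moderate_power, dtype=float)
    for c in range(10):
        p[(5 * c) // 2] = 0.5 * (spec.high_power + spec.moderate_power)
    return p


def _opportunistic_power(spec: ProtocolSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = OPPORTUNISTIC_POWER[spec.kind]
    n = spec.duration
    p = np.zeros(n)
    bm = spec.break_model
    # active blocks are capped at a third of the session and breaks last
    # at least 3 minutes, so an opportunistic session always carries a
    # recognizable break structure (the behaviour being modelled)
    max_active = max(5, n // 3) if bm.enabled else n
    t, active = 0, True
    while t < n:
        if active:
            length = min(int(rng.geometric(1.0 / bm.mean_active_minutes)),
                         max_active, n - t)
            base = rng.uniform(lo, hi)
            block = base + rng.normal(0.0, 4.0, length)
            p[t:t + length] = np.clip(block, 10.0, None)
        else:
            mean_tail = max(bm.mean_break_minutes - 2.0, 1.0)
            length = min(2 + int(rng.geometric(1.0 / mean_tail)), n - t)
        t += length
        if bm.enabled:
            active = not active
    return p


def _protocol_power(spec: ProtocolSpec, participant: ParticipantModel,
                    rng: np.random.Generator) -> np.ndarray:
    if spec.kind in ("mict", "dosed_mict"):
        p = hr_controller(spec.target_hr_band, participant, spec.duration)
    elif spec.kind == "hiit_wingate":
        p = _hiit_power(spec)
    else:
        p = _opportunistic_power(spec, rng)
    if spec.truncate_minutes is not None:
        p = p[:spec.truncate_minutes]
    return p


# ---------------------------------------------------------------------------
# session / week / cohort simulation


def _session_channels(power: np.ndarray, spec: ProtocolSpec,
                      participant: ParticipantModel, rng: np.random.Generator,
                      noise_scale: float):
    """HR / SpO2 / BP arrays for one session (length ``len(power) + 1``)."""
    n = power.size
    include_hr = spec.kind in ("mict", "dosed_mict", "hiit_wingate")
    hr = spo2 = sys_bp = dia_bp = None
    if include_hr:
        hrp = replace(participant.hr,
                      hr_noise_sd=participant.hr.hr_noise_sd * noise_scale)
        hr = np.concatenate([[hrp.hr_rest], simulate_hr(power, hrp, rng)])
        spo2 = participant.spo2_baseline + rng.normal(0.0, SPO2_NOISE_SD * noise_scale, n + 1)
        spo2 = np.clip(spo2, 50.0, 100.0)
    if spec.kind in ("mict", "dosed_mict"):
        active_min = np.concatenate([[0.0], np.cumsum(power > 0)])
        sys_bp = participant.systolic_baseline + participant.bp_exercise_slope * active_min / 10.0
        dia_bp = participant.diastolic_baseline + 0.3 * participant.bp_exercise_slope * active_min / 10.0
    return hr, spo2, sys_bp, dia_bp


def simulate_protocol(spec: ProtocolSpec, participant: ParticipantModel,
                      start, noise_scale: float = 1.0,
                      rng=None) -> SimulatedSession:
    """Simulate one session and return zeroed telemetry plus ground truth.

    The series holds ``effective_duration + 1`` samples: the zeroing
    sample at session start (temperature exactly 0) followed by one
    reading at the end of each exercised minute.  HR and SpO2 are
    recorded for the dedicated kinds only, mirroring a pulse-oximeter
    worn during prescribed bouts; opportunistic traces are
    temperature-only.
    """
    start = pd.Timestamp(start)
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    power = _protocol_power(spec, participant, rng)
    n = power.size
    temp = np.concatenate([[0.0], simulate_thermal(power, participant.thermal)])
    if noise_scale > 0:
        temp[1:] += rng.normal(0.0, TEMP_NOISE_SD * noise_scale, n)
    hr, spo2, sys_bp, dia_bp = _session_channels(power, spec, participant, rng, noise_scale)

    ts = start + pd.to_timedelta(np.arange(n + 1), unit="min")
    session_id = f"{participant.participant_id}-{start.strftime('%Y%m%dT%H%M')}"
    series = TelemetrySeries.from_arrays(
        participant.participant_id, ts, temp,
        heart_rate=hr, spo2=spo2, systolic=sys_bp, diastolic=dia_bp, zeroed=True)
    boundary = SessionBoundary(ts[0], ts[-1], zero_reference=0.0, session_id=session_id)
    activity = ActivityTrace(session_id, spec.kind, ts[:-1], power, power > 0)
    return SimulatedSession(series, boundary, activity)


def simulate_week(schedule: Sequence[ScheduledSession],
                  participant: ParticipantModel, start, seed: int = 0,
                  noise_scale: float = 1.0,
                  ambient_absolute: float = 22.0) -> SimulatedWeek:
    """Simulate a continuous 7-day absolute-temperature recording.

    Sessions are placed on their scheduled days, the device relaxes to
    ambient between them, and every session gets a boundary whose
    ``zero_reference`` is the recorded temperature at its first sample —
    reproducing per-session zeroing over one uninterrupted weekly trace.
    """
    week_start = pd.Timestamp(start).normalize()
    n_min = 7 * 1440 + 1

    entries = sorted(schedule, key=lambda e: (e.day, e.start_time))
    offsets = []
    for e in entries:
        off = (e.day - 1) * 1440 + e.start_time.hour * 60 + e.start_time.minute
        dur = e.spec.effective_duration
        if off + dur > n_min - 1:
            raise SchedulingError(f"session on day {e.day} runs past the week end")
        offsets.append((off, dur, e))
    for (o1, d1, e1), (o2, _, e2) in zip(offsets, offsets[1:]):
        if o2 <= o1 + d1:
            raise SchedulingError(
                f"sessions on day {e1.day} and day {e2.day} overlap")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(entries) + 1)
    noise_rng = np.random.default_rng(children[0])

    power = np.zeros(n_min - 1)
    session_payload = []
    for (off, dur, e), child in zip(offsets, children[1:]):
        rng = np.random.default_rng(child)
        p = _protocol_power(e.spec, participant, rng)
        power[off:off + p.size] = p
        session_payload.append((off, p, e, rng))

    base = ambient_absolute + participant.thermal.ambient_offset
    temp = base + np.concatenate([[0.0], simulate_thermal(
        power, replace(participant.thermal, ambient_offset=0.0))])
    if noise_scale > 0:
        temp = temp + noise_rng.normal(0.0, TEMP_NOISE_SD * noise_scale, n_min)

    ts = week_start + pd.to_timedelta(np.arange(n_min), unit="min")
    hr_col = np.full(n_min, np.nan)
    spo2_col = np.full(n_min, np.nan)
    sys_col = np.full(n_min, np.nan)
    dia_col = np.full(n_min, np.nan)

    boundaries, activities = [], []
    for idx, (off, p, e, rng) in enumerate(session_payload):
        n = p.size
        hr, spo2, sys_bp, dia_bp = _session_channels(p, e.spec, participant, rng, noise_scale)
        sl = slice(off, off + n + 1)
        if hr is not None:
            hr_col[sl], spo2_col[sl] = hr, spo2
        if sys_bp is not None:
            sys_col[sl], dia_col[sl] = sys_bp, dia_bp
        session_id = f"{participant.participant_id}-d{e.day}s{idx}"
        boundaries.append(SessionBoundary(
            ts[off], ts[off + n], zero_reference=float(temp[off]),
            session_id=session_id))
        activities.append(ActivityTrace(session_id, e.spec.kind,
                                        ts[off:off + n], p, p > 0))

    series = TelemetrySeries.from_arrays(
        participant.participant_id, ts, temp, heart_rate=hr_col,
        spo2=spo2_col, systolic=sys_col, diastolic=dia_col, zeroed=False)
    return SimulatedWeek(series, boundaries, activities)


def dosed_week_schedule(days: Sequence[int], duration: int = 35,
                        target_hr_band: tuple[float, float] = (100.0, 10.0),
                        start_time: dtime = dtime(9, 0)) -> list[ScheduledSession]:
    """Schedule one moderate continuous session on each listed day (1..7).

    The default 35-minute duration models a user who keeps pedalling a few
    minutes past the 30-minute dose point (until the alert fires), so a
    calibrated threshold is reached reliably under measurement noise.
    """
    return [ScheduledSession(day=int(d),
                             spec=ProtocolSpec(kind="mict", duration=duration,
                                               target_hr_band=target_hr_band),
                             start_time=start_time)
            for d in sorted(set(int(d) for d in days))]


#: Default cohort heterogeneity: heat coefficients spanning 30-minute dosed
#: doses of about 4.5–10.5 degC for the default HR/controller parameters.
DEFAULT_HETEROGENEITY = {"heat_coefficient": (0.00414, 0.00965)}


def simulate_cohort(n: int, heterogeneity: Optional[dict] = None,
                    seed: int = 0) -> list[ParticipantModel]:
    """Draw ``n`` participant models with uniform parameter heterogeneity.

    ``heterogeneity`` maps flat profile keys (``heat_coefficient``,
    ``cooling_rate``, ``hr_rest``, ...) to ``(low, high)`` ranges; keys not
    listed stay at their defaults.  Reproducible for a fixed seed.
    """
    from .telemetry_io import _PROFILE_KEYS

    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    ranges = dict(DEFAULT_HETEROGENEITY if heterogeneity is None else heterogeneity)
    for key, (lo, hi) in ranges.items():
        if key not in _PROFILE_KEYS:
            raise ValidationError(f"unknown heterogeneity key {key!r}")
        if lo > hi:
            raise ValidationError(f"degenerate range for {key!r}: {lo} > {hi}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        thermal_kw, hr_kw, top_kw = {}, {}, {}
        for key, (lo, hi) in sorted(ranges.items()):
            value = float(rng.uniform(lo, hi))
            group, attr = _PROFILE_KEYS[key]
            if group == "thermal":
                thermal_kw[attr] = value
            elif group == "hr":
                hr_kw[attr] = value
            else:
                top_kw[attr] = value
        cohort.append(ParticipantModel(
            participant_id=f"P{i + 1:02d}",
            thermal=ThermalParams(**thermal_kw), hr=HRParams(**hr_kw), **top_kw))
    return cohort
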