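"""Per-session metrics from raw telemetry.

Turns a telemetry slice into the session-relative temperature-rise trace,
segments it into active bouts from the trace slope, classifies the regimen
with deterministic rules, totals mobilization minutes and, when thermal
parameters are known, inverts the device model to estimate per-minute
mechanical power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .device_simulator import ThermalParams
from .errors import OutOfRangeError, ValidationError
from .telemetry_io import SessionBoundary, TelemetrySeries

#: Segmentation defaults; the underlying study never fixes these numerically.
SLOPE_THRESHOLD = 0.05   # degC/min, raw-slope activity threshold
RISE_EPS = 0.01          # degC/min, "still rising after smoothing" floor
MERGE_GAP = 5            # minutes
MIN_LEN = 3              # minutes
SMOOTH_WINDOW = 3        # samples, centered moving average

REGIMEN_LABELS = ("MICT", "HIIT", "opportunistic", "unknown")


@dataclass(frozen=True)
class Bout:
    """One contiguous run of active training minutes."""

    start: pd.Timestamp
    end: pd.Timestamp
    peak_delta_t: float
    active_minutes: int
    mean_hr: Optional[float] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError("bout start must precede end")
        if self.peak_delta_t < 0:
            raise ValidationError("peak_delta_t must be >= 0")


@dataclass(frozen=True)
class SessionMetrics:
    participant_id: str
    boundary: SessionBoundary
    delta_t: pd.Series
    bouts: list[Bout]
    regimen: str
    mobilization_minutes: int
    hr: Optional[pd.Series] = None
    est_power: Optional[pd.Series] = None

    @property
    def peak_delta_t(self) -> float:
        return float(self.delta_t.max()) if len(self.delta_t) else 0.0


# ---------------------------------------------------------------------------


def compute_delta_t(series: TelemetrySeries, boundary: SessionBoundary) -> pd.Series:
    """Session-relative temperature rise on the minutes present in-session.

    Subtracts the boundary's zeroing reference; no interpolation over
    missing minutes.  The first in-session value is exactly zero whenever
    the reference equals the first sample (the recording convention).
    """
    idx = series.frame.index
    if len(idx) == 0 or boundary.start < idx[0] or boundary.end > idx[-1]:
        raise OutOfRangeError(
            f"session [{boundary.start}, {boundary.end}] outside telemetry range")
    window = series.frame.loc[boundary.start:boundary.end, "temperature_c"]
    delta = window - boundary.zero_reference
    delta.name = "delta_t_c"
    return delta


def _minutes(index: pd.DatetimeIndex) -> np.ndarray:
    return (index - index[0]).total_seconds().to_numpy() / 60.0


def _smooth(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    return (pd.Series(values).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def detect_bouts(delta_t: pd.Series, slope_threshold: float = SLOPE_THRESHOLD,
                 merge_gap: float = MERGE_GAP, min_len: int = MIN_LEN,
                 hr: Optional[pd.Series] = None,
                 rise_eps: float = RISE_EPS) -> list[Bout]:
    """Segment a rise trace into active bouts.

    A minute is active when the centered finite-difference slope of the
    raw trace reaches ``slope_threshold`` OR the smoothed trace is still
    rising (slope at least ``rise_eps`` — pedalling near the device's
    thermal equilibrium produces a small but sustained rise, while breaks
    cool it).  Active runs whose separating gap is shorter than
    ``merge_gap`` minutes are merged; runs with fewer than ``min_len``
    active minutes are discarded.
    """
    if slope_threshold <= 0 or merge_gap <= 0 or min_len <= 0:
        raise ValidationError("segmentation thresholds must be positive")
    if len(delta_t) < 2:
        return []
    v = delta_t.to_numpy(dtype=float)
    t = _minutes(delta_t.index)
    slope_raw = np.gradient(v, t)
    slope_sm = np.gradient(_smooth(v), t)
    active = (slope_raw >= slope_threshold) | (slope_sm >= rise_eps)

    runs = _runs(active)
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and t[i0] - t[merged[-1][1]] < merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    bouts = []
    for i0, i1 in merged:
        n_active = int(np.count_nonzero(active[i0:i1 + 1]))
        if n_active < min_len:
            continue
        span = slice(i0, i1 + 1)
        mean_hr = None
        if hr is not None:
            in_span = hr.loc[delta_t.index[i0]:delta_t.index[i1]].dropna()
            if len(in_span):
                mean_hr = float(in_span.mean())
        bouts.append(Bout(start=delta_t.index[i0], end=delta_t.index[i1],
                          peak_delta_t=max(0.0, float(np.max(v[span]))),
                          active_minutes=n_active, mean_hr=mean_hr))
    return bouts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i0, i1] of consecutive True entries."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def classify_regimen(bouts: Sequence[Bout], delta_t: pd.Series,
                     hr: Optional[pd.Series] = None, *,
                     hiit_min_alternations: int = 6,
                     hiit_min_swing: float = 0.2,
                     hiit_max_run: float = 3.5,
                     mict_cv_cutoff: float = 1.0,
                     mict_dominance: float = 0.8,
                     decay_slope: float = -0.05) -> str:
    """Deterministic rule-based regimen label.

    HIIT: some bout alternates at least ``hiit_min_alternations`` times
    between high and moderate slope states (hysteresis bands around the
    detrended mid-slope, swing at least ``hiit_min_swing`` degC/min,
    short state runs).  MICT: one bout dominates the active minutes and
    the session shows no cooling episodes (the device never relaxes
    mid-session during continuous training — a saturated plateau is fine,
    a break is not) with a bounded coefficient of variation of the active
    slope.  Anything else with bouts is opportunistic; ``unknown`` when
    no rule fires.
    """
    if not bouts:
        raise ValidationError("classify_regimen requires at least one bout")
    v = delta_t.to_numpy(dtype=float)
    t = _minutes(delta_t.index)
    slope = np.gradient(v, t)
    slope_sm = np.gradient(_smooth(v), t)

    for bout in bouts:
        mask = (delta_t.index >= bout.start) & (delta_t.index <= bout.end)
        if _is_interval_pattern(slope[mask], hiit_min_alternations,
                                hiit_min_swing, hiit_max_run):
            return "HIIT"

    total_active = sum(b.active_minutes for b in bouts)
    dominant = max(bouts, key=lambda b: b.active_minutes)
    bout_span = (dominant.end - dominant.start).total_seconds() / 60.0
    decay_minutes = int(np.count_nonzero(slope_sm <= decay_slope))
    decay_limit = max(2, int(0.04 * slope_sm.size))

    continuous = (dominant.active_minutes >= mict_dominance * total_active
                  and 8.0 <= bout_span <= 135.0
                  and decay_minutes <= decay_limit)
    if continuous:
        mask = (delta_t.index >= dominant.start) & (delta_t.index <= dominant.end)
        sl = slope[mask]
        sl = sl[sl >= SLOPE_THRESHOLD]
        if sl.size and sl.std() / sl.mean() < mict_cv_cutoff:
            return "MICT"
        return "unknown"
    return "opportunistic"


def _is_interval_pattern(slopes: np.ndarray, min_alternations: int,
                         min_swing: float, max_run: float) -> bool:
    if slopes.size < 8:
        return False
    # remove the saturation trend so the high/moderate alternation is
    # judged against the local slope level, not the whole-session range
    trend = (pd.Series(slopes).rolling(5, center=True, min_periods=1)
             .mean().to_numpy())
    resid = slopes - trend
    p10, p90 = np.percentile(resid, [10, 90])
    swing = p90 - p10
    if swing < min_swing:
        return False
    mid = 0.5 * (p10 + p90)
    hys = 0.2 * swing
    state = 0  # -1 low, +1 high
    transitions = 0
    run_lengths: list[int] = []
    run = 0
    for s in resid:
        new = 1 if s >= mid + hys else (-1 if s <= mid - hys else state)
        if new != state and new != 0:
            if state != 0:
                transitions += 1
                run_lengths.append(run)
            state, run = new, 0
        run += 1
    if transitions < min_alternations:
        return False
    return float(np.mean(run_lengths)) <= max_run


def estimate_power(delta_t: pd.Series, params: ThermalParams) -> pd.Series:
    """Invert the thermal model to estimate per-minute power.

    ``P(t) = (d(delta_t)/dt + lambda * (delta_t - ambient_offset)) / k``
    with centered finite differences in the interior, one-sided at the
    edges, floored at zero.
    """
    if params.heat_coefficient <= 0:
        raise ValidationError("heat_coefficient must be > 0")
    if len(delta_t) < 2:
        raise ValidationError("need at least two samples to estimate power")
    v = delta_t.to_numpy(dtype=float)
    t = _minutes(delta_t.index)
    deriv = np.gradient(v, t)
    p = (deriv + params.cooling_rate * (v - params.ambient_offset)) / params.heat_coefficient
    return pd.Series(np.maximum(p, 0.0), index=delta_t.index, name="est_power_w")


def mobilization_minutes(bouts: Sequence[Bout]) -> int:
    """Total active minutes summed over bouts (order-invariant, additive)."""
    return int(sum(b.active_minutes for b in bouts))


def analyze_session(series: TelemetrySeries, boundary: SessionBoundary,
                    thermal: Optional[ThermalParams] = None,
                    slope_threshold: float = SLOPE_THRESHOLD,
                    merge_gap: float = MERGE_GAP,
                    min_len: int = MIN_LEN) -> SessionMetrics:
    """Full per-session analysis: rise trace, bouts, label, mobilization."""
    delta = compute_delta_t(series, boundary)
    hr_window = series.frame.loc[boundary.start:boundary.end, "heart_rate_bpm"]
    hr = hr_window if hr_window.notna().any() else None
    bouts = detect_bouts(delta, slope_threshold, merge_gap, min_len, hr=hr)
    regimen = classify_regimen(bouts, delta, hr) if bouts else "unknown"
    est = estimate_power(delta, thermal) if thermal is not None and len(delta) > 1 else None
    return SessionMetrics(
        participant_id=series.participant_id, boundary=boundary, delta_t=delta,
        bouts=bouts, regimen=regimen,
        mobilization_minutes=mobilization_minutes(bouts), hr=hr, est_power=est)


def infer_boundaries(series: TelemetrySeries, gap_minutes: float = 60.0) -> list[SessionBoundary]:
    """Simple boundary heuristic for gapped recordings: a new session
    starts after a gap longer than ``gap_minutes``.  Continuous multi-day
    traces need an explicit boundary file instead."""
    idx = series.frame.index
    if len(idx) == 0:
        return []
    gaps = np.diff(idx.to_numpy()) / np.timedelta64(1, "m")
    starts = [0] + [i + 1 for i, g in enumerate(gaps) if g > gap_minutes]
    ends = [s - 1 for s in starts[1:]] + [len(idx) - 1]
    out = []
    for n, (s, e) in enumerate(zip(starts, ends)):
        if e <= s:
            continue
        out.append(SessionBoundary(
            idx[s], idx[e],
            zero_reference=float(series.frame["temperature_c"].iloc[s]),
            session_id=f"{series.participant_id}-auto{n}"))
    return out
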