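"""Personalized exercise doses, notification events and weekly adherence.

The daily dose is the session-relative temperature rise a participant
produces in 30 minutes of moderate continuous training at the calibration
heart-rate band.  Each day the first minute at which any session's rise
reaches the threshold emits one notification event (debounced per
calendar day), and a week is compliant when doses were taken on at least
five days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import CalibrationError, OutOfRangeError, ValidationError
from .session_analysis import SessionMetrics, compute_delta_t
from .telemetry_io import SessionBoundary, TelemetrySeries

#: Weekly compliance rule: doses taken on at least this many days.
COMPLIANT_MIN_DAYS = 5

CALIBRATION_MINUTES = 30
DEFAULT_BAND = (100.0, 10.0)


@dataclass(frozen=True)
class DosePrescription:
    participant_id: str
    dose_threshold: float            # degC
    calibrated_at: pd.Timestamp
    calibration_session_id: str = ""
    target_hr_band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self):
        if not self.dose_threshold > 0:
            raise ValidationError("dose_threshold must be > 0")
        object.__setattr__(self, "calibrated_at", pd.Timestamp(self.calibrated_at))


@dataclass(frozen=True)
class NotificationEvent:
    """Stand-in for one threshold-crossing email alert."""

    participant_id: str
    timestamp: pd.Timestamp
    day: dt.date
    dose_threshold: float


@dataclass(frozen=True)
class AdherenceReport:
    participant_id: str
    week_start: dt.date
    day_flags: tuple[bool, bool, bool, bool, bool, bool, bool]
    dose_days: int
    compliant: bool
    incomplete_bouts: int = 0

    def __post_init__(self):
        if len(self.day_flags) != 7:
            raise ValidationError("day_flags must have exactly 7 entries")
        if self.dose_days != sum(self.day_flags):
            raise ValidationError("dose_days must equal the number of ticked days")
        if self.compliant != (self.dose_days >= COMPLIANT_MIN_DAYS):
            raise ValidationError(
                f"compliant flag must follow the >= {COMPLIANT_MIN_DAYS}-day rule")


# ---------------------------------------------------------------------------


def calibrate_dose(calibration: SessionMetrics,
                   duration: int = CALIBRATION_MINUTES,
                   min_band_fraction: float = 0.8) -> DosePrescription:
    """Personalized dose from one moderate continuous calibration session.

    The threshold is the session-relative rise at minute ``duration``.
    The session must be classified MICT, last at least ``duration``
    minutes and — when heart rate was recorded — keep at least
    ``min_band_fraction`` of its readings inside the target band.
    """
    if calibration.regimen != "MICT":
        raise CalibrationError(
            f"calibration session classified {calibration.regimen!r}, need MICT")
    delta = calibration.delta_t
    start = calibration.boundary.start
    target_ts = start + pd.Timedelta(minutes=duration)
    if len(delta) == 0 or delta.index[-1] < target_ts:
        raise CalibrationError(
            f"calibration session shorter than {duration} minutes")
    band = DEFAULT_BAND
    if calibration.hr is not None:
        lo, hi = band[0] - band[1], band[0] + band[1]
        hr = calibration.hr.dropna()
        # settle-in minutes excluded: self-paced control needs a short ramp
        hr = hr[hr.index >= start + pd.Timedelta(minutes=5)]
        if len(hr) and (hr.between(lo, hi).mean() < min_band_fraction):
            raise CalibrationError(
                f"heart rate inside {lo:.0f}-{hi:.0f} BPM less than "
                f"{min_band_fraction:.0%} of the session")
    window = delta.loc[:target_ts]
    if window.index[-1] < target_ts - pd.Timedelta(minutes=1):
        raise CalibrationError(f"no sample at calibration minute {duration}")
    value = float(window.iloc[-1])
    if value <= 0:
        raise CalibrationError("non-positive rise at the calibration minute")
    return DosePrescription(
        participant_id=calibration.participant_id, dose_threshold=value,
        calibrated_at=target_ts,
        calibration_session_id=calibration.boundary.session_id,
        target_hr_band=band)


def progress_fraction(current_delta_t: float, prescription: DosePrescription) -> float:
    """Fraction of the daily dose achieved, capped at 1.0 once exceeded."""
    if current_delta_t < 0:
        raise ValidationError("current_delta_t must be >= 0")
    return min(current_delta_t / prescription.dose_threshold, 1.0)


def detect_dose_events(series: TelemetrySeries,
                       boundaries: Sequence[SessionBoundary],
                       prescription: DosePrescription) -> list[NotificationEvent]:
    """Threshold-crossing notifications, at most one per calendar day.

    Each session contributes the first minute at which its rise reaches
    the threshold (inclusive); a day with several completed sessions still
    emits a single event, credited at the earliest crossing.
    """
    crossings = []
    for boundary in sorted(boundaries, key=lambda b: b.start):
        delta = compute_delta_t(series, boundary)
        hits = delta[delta >= prescription.dose_threshold]
        if len(hits):
            crossings.append(hits.index[0])
    events: dict[dt.date, pd.Timestamp] = {}
    for ts in crossings:
        day = ts.date()
        if day not in events or ts < events[day]:
            events[day] = ts
    return [NotificationEvent(prescription.participant_id, ts, day,
                              prescription.dose_threshold)
            for day, ts in sorted(events.items())]


def detect_incomplete_bouts(sessions: Sequence[SessionMetrics],
                            prescription: DosePrescription
                            ) -> tuple[int, list[str]]:
    """MICT sessions whose peak rise never reached the dose threshold."""
    flagged = [m.boundary.session_id for m in sessions
               if m.regimen == "MICT"
               and m.peak_delta_t < prescription.dose_threshold]
    return len(flagged), flagged


def weekly_adherence(events: Sequence[NotificationEvent], week_start,
                     participant_id: str,
                     incomplete_bouts: int = 0) -> AdherenceReport:
    """Tick/cross flags for the 7 days starting at ``week_start``."""
    week_start = pd.Timestamp(week_start).date()
    flags = [False] * 7
    for event in events:
        offset = (event.day - week_start).days
        if not 0 <= offset < 7:
            raise OutOfRangeError(
                f"event on {event.day} outside week starting {week_start}")
        flags[offset] = True
    dose_days = sum(flags)
    return AdherenceReport(
        participant_id=participant_id, week_start=week_start,
        day_flags=tuple(flags), dose_days=dose_days,
        compliant=dose_days >= COMPLIANT_MIN_DAYS,
        incomplete_bouts=incomplete_bouts)


@dataclass(frozen=True)
class CohortTable:
    """Supervisor view: participants x day flags plus weekly verdicts."""

    reports: tuple[AdherenceReport, ...]

    @property
    def n_compliant(self) -> int:
        return sum(r.compliant for r in self.reports)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            row = {"participant_id": r.participant_id,
                   "week_start": r.week_start.isoformat()}
            for d in range(7):
                row[f"day{d + 1}"] = "x" if r.day_flags[d] else "."
            row["dose_days"] = r.dose_days
            row["compliant"] = r.compliant
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"{'participant':<14}" + "".join(f" d{d + 1}" for d in range(7))
                 + "  days  compliant"]
        for r in self.reports:
            ticks = "".join(f"  {'x' if f else '.'}" for f in r.day_flags)
            lines.append(f"{r.participant_id:<14}{ticks}  {r.dose_days:>4}  "
                         f"{'yes' if r.compliant else 'no'}")
        lines.append(f"compliant: {self.n_compliant}/{len(self.reports)}")
        return "\n".join(lines)


def cohort_report(reports: Sequence[AdherenceReport]) -> CohortTable:
    """Aggregate weekly reports; one row per participant-week."""
    seen = set()
    for r in reports:
        key = (r.participant_id, r.week_start)
        if key in seen:
            raise ValidationError(f"duplicate participant-week {key}")
        seen.add(key)
    return CohortTable(tuple(reports))


def write_event_log(events: Sequence[NotificationEvent], path,
                    append: bool = True) -> Path:
    """Append notification events to a CSV log (the email stand-in)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "participant_id,timestamp,day,dose_threshold_c\n"
    new_file = not path.exists() or not append
    with path.open("a" if append else "w", encoding="utf-8") as fh:
        if new_file or path.stat().st_size == 0:
            fh.write(header)
        for e in events:
            fh.write(f"{e.participant_id},{e.timestamp.strftime('%Y-%m-%dT%H:%M:%S')},"
                     f"{e.day.isoformat()},{e.dose_threshold}\n")
    return path


def read_event_log(path) -> list[NotificationEvent]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return [NotificationEvent(
        participant_id=str(r.participant_id),
        timestamp=pd.Timestamp(r.timestamp),
        day=pd.Timestamp(r.day).date(),
        dose_threshold=float(r.dose_threshold_c)) for r in df.itertuples()]
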