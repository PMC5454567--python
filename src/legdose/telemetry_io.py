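"""Readers, writers and the in-memory model for minute-resolution telemetry.

On-disk dialect
---------------
Telemetry files are plain CSV with a fixed header::

    timestamp,temperature_c,heart_rate_bpm,spo2_pct,systolic_mmhg,diastolic_mmhg

Timestamps are ISO-8601 local date-times without a timezone suffix
(``2026-01-05T09:00:00``), one row per minute.  Missing minutes are absent
rows, missing optional channels are empty cells.  Zero or more leading
comment lines of the form ``# key=value`` carry series metadata
(``participant_id``, ``zeroed``).

Session boundaries, participant profiles and prescriptions are small
flat JSON files; see :func:`read_boundaries` and :func:`read_profile`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Channel columns in file order (timestamp is the index).
CHANNELS = (
    "temperature_c",
    "heart_rate_bpm",
    "spo2_pct",
    "systolic_mmhg",
    "diastolic_mmhg",
)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

HR_RANGE = (20.0, 250.0)
SPO2_RANGE = (50.0, 100.0)


@dataclass(frozen=True)
class TelemetrySample:
    """One minute-stamped multichannel reading."""

    timestamp: pd.Timestamp
    temperature: float
    heart_rate: Optional[float] = None
    spo2: Optional[float] = None
    systolic: Optional[float] = None
    diastolic: Optional[float] = None


@dataclass(frozen=True)
class SessionBoundary:
    """Start/end of one training session plus its zeroing reference.

    ``zero_reference`` is the temperature of the first in-session sample;
    subtracting it reproduces the session-relative temperature-rise trace.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    zero_reference: float = 0.0
    session_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValidationError(
                f"session boundary start {self.start} must precede end {self.end}"
            )


class TelemetrySeries:
    """Ordered minute telemetry for one participant.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    frame : pandas.DataFrame
        Indexed by timestamp, with the columns of :data:`CHANNELS`
        (missing columns are added as all-NaN).
    zeroed : bool
        ``True`` when temperatures are session-relative (zeroed at each
        session start); ``False`` for raw absolute traces.
    """

    def __init__(self, participant_id: str, frame: pd.DataFrame, *,
                 zeroed: bool = True,
                 sampling_interval: pd.Timedelta = pd.Timedelta(minutes=1),
                 validate: bool = True):
        frame = frame.copy()
        for col in CHANNELS:
            if col not in frame.columns:
                frame[col] = np.nan
        frame = frame[list(CHANNELS)].astype(float)
        frame.index = pd.DatetimeIndex(frame.index, name="timestamp")
        self.participant_id = str(participant_id)
        self.frame = frame
        self.zeroed = bool(zeroed)
        self.sampling_interval = pd.Timedelta(sampling_interval)
        if validate:
            self._validate()

    def _validate(self) -> None:
        idx = self.frame.index
        if len(idx) and not (idx.is_monotonic_increasing and idx.is_unique):
            raise ValidationError("timestamps must be strictly increasing")
        t = self.frame["temperature_c"].to_numpy()
        if len(t) and not np.isfinite(t).all():
            raise ValidationError("temperature must be finite for every sample")
        hr = self.frame["heart_rate_bpm"].to_numpy()
        bad = np.isfinite(hr) & ((hr < HR_RANGE[0]) | (hr > HR_RANGE[1]))
        if bad.any():
            raise ValidationError(f"heart rate outside {HR_RANGE} in {bad.sum()} rows")
        sp = self.frame["spo2_pct"].to_numpy()
        bad = np.isfinite(sp) & ((sp < SPO2_RANGE[0]) | (sp > SPO2_RANGE[1]))
        if bad.any():
            raise ValidationError(f"SpO2 outside {SPO2_RANGE} in {bad.sum()} rows")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_arrays(cls, participant_id: str, timestamps, temperature, *,
                    heart_rate=None, spo2=None, systolic=None, diastolic=None,
                    zeroed: bool = True) -> "TelemetrySeries":
        data = {"temperature_c": np.asarray(temperature, dtype=float)}
        for col, values in (("heart_rate_bpm", heart_rate), ("spo2_pct", spo2),
                            ("systolic_mmhg", systolic), ("diastolic_mmhg", diastolic)):
            data[col] = np.nan if values is None else np.asarray(values, dtype=float)
        frame = pd.DataFrame(data, index=pd.DatetimeIndex(timestamps, name="timestamp"))
        return cls(participant_id, frame, zeroed=zeroed)

    @classmethod
    def from_samples(cls, participant_id: str,
                     samples: Iterable[TelemetrySample],
                     zeroed: bool = True) -> "TelemetrySeries":
        samples = list(samples)
        return cls.from_arrays(
            participant_id,
            [s.timestamp for s in samples],
            [s.temperature for s in samples],
            heart_rate=[np.nan if s.heart_rate is None else s.heart_rate for s in samples],
            spo2=[np.nan if s.spo2 is None else s.spo2 for s in samples],
            systolic=[np.nan if s.systolic is None else s.systolic for s in samples],
            diastolic=[np.nan if s.diastolic is None else s.diastolic for s in samples],
            zeroed=zeroed,
        )

    # -- accessors ------------------------------------------------------

    @property
    def samples(self) -> list[TelemetrySample]:
        out = []
        for ts, row in self.frame.iterrows():
            vals = {c: (None if pd.isna(row[c]) else float(row[c])) for c in CHANNELS}
            out.append(TelemetrySample(
                timestamp=ts, temperature=vals["temperature_c"],
                heart_rate=vals["heart_rate_bpm"], spo2=vals["spo2_pct"],
                systolic=vals["systolic_mmhg"], diastolic=vals["diastolic_mmhg"]))
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TelemetrySeries):
            return NotImplemented
        return (self.participant_id == other.participant_id
                and self.zeroed == other.zeroed
                and self.frame.equals(other.frame))

    def __repr__(self) -> str:
        return (f"TelemetrySeries(participant_id={self.participant_id!r}, "
                f"n={len(self)}, zeroed={self.zeroed})")


# ---------------------------------------------------------------------------
# telemetry CSV


def read_telemetry(path, strict: bool = True) -> TelemetrySeries:
    """Read a telemetry CSV file.

    In strict mode any row violating the sample invariants (duplicate or
    out-of-order timestamp, non-finite temperature, out-of-range HR/SpO2)
    raises :class:`ValidationError`; in lenient mode offending rows are
    dropped and the count is logged.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        skip = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                skip += 1
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            break
        fh.seek(pos)
        df = pd.read_csv(fh, skiprows=skip, dtype=str, keep_default_na=False)

    expected = ["timestamp", *CHANNELS]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: malformed header {list(df.columns)!r}, expected {expected!r}")

    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    dropped = 0

    bad_ts = ts.isna()
    if bad_ts.any():
        if strict:
            raise ValidationError(f"{path}: {bad_ts.sum()} unparseable timestamps")
        dropped += int(bad_ts.sum())
        df, ts = df[~bad_ts], ts[~bad_ts]

    def _exact_float(v: str) -> float:
        # Python's float() is correctly rounded, so values written via
        # repr() round-trip bit-exactly (pandas' fast parser may be 1 ulp off)
        if v == "":
            return np.nan
        try:
            return float(v)
        except ValueError:
            return np.nan

    values = {}
    for col in CHANNELS:
        values[col] = df[col].map(_exact_float).astype(float)
    frame = pd.DataFrame(values)
    frame.index = pd.DatetimeIndex(ts, name="timestamp")

    # row-level invariants
    bad = ~np.isfinite(frame["temperature_c"].to_numpy())
    hr = frame["heart_rate_bpm"].to_numpy()
    bad |= np.isfinite(hr) & ((hr < HR_RANGE[0]) | (hr > HR_RANGE[1]))
    sp = frame["spo2_pct"].to_numpy()
    bad |= np.isfinite(sp) & ((sp < SPO2_RANGE[0]) | (sp > SPO2_RANGE[1]))
    if bad.any():
        if strict:
            raise ValidationError(f"{path}: {bad.sum()} rows violate sample invariants")
        dropped += int(bad.sum())
        frame = frame[~bad]

    if not frame.index.is_unique or not frame.index.is_monotonic_increasing:
        if strict:
            raise ValidationError(f"{path}: duplicate or out-of-order timestamps")
        before = len(frame)
        frame = frame.sort_index(kind="stable")
        frame = frame[~frame.index.duplicated(keep="first")]
        dropped += before - len(frame)

    if dropped:
        logger.warning("%s: dropped %d invalid rows (lenient mode)", path, dropped)

    zeroed = meta.get("zeroed", "true").lower() != "false"
    return TelemetrySeries(meta.get("participant_id", "unknown"), frame, zeroed=zeroed)


def write_telemetry(series: TelemetrySeries, path) -> Path:
    """Write ``series`` to ``path`` in the documented CSV dialect.

    The output round-trips losslessly through :func:`read_telemetry` and
    rewriting a read series is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# participant_id={series.participant_id}\n")
        fh.write(f"# zeroed={'true' if series.zeroed else 'false'}\n")
        series.frame.to_csv(fh, date_format=TIMESTAMP_FORMAT, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# session boundaries


def write_boundaries(boundaries: list[SessionBoundary], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"session_id": b.session_id,
             "start": b.start.strftime(TIMESTAMP_FORMAT),
             "end": b.end.strftime(TIMESTAMP_FORMAT),
             "zero_reference_c": b.zero_reference} for b in boundaries]
    pd.DataFrame(rows, columns=["session_id", "start", "end", "zero_reference_c"]) \
        .to_csv(path, index=False, lineterminator="\n")
    return path


def read_boundaries(path) -> list[SessionBoundary]:
    df = pd.read_csv(path, dtype={"session_id": str})
    required = {"session_id", "start", "end", "zero_reference_c"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: boundary file must have columns {sorted(required)}")
    return [SessionBoundary(start=pd.Timestamp(r.start), end=pd.Timestamp(r.end),
                            zero_reference=float(r.zero_reference_c),
                            session_id=str(r.session_id))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# participant profiles (flat JSON)

#: Flat profile keys -> (dataclass, attribute) mapping used by read/write.
_PROFILE_KEYS = {
    "heat_coefficient": ("thermal", "heat_coefficient"),
    "cooling_rate": ("thermal", "cooling_rate"),
    "ambient_offset": ("thermal", "ambient_offset"),
    "hr_rest": ("hr", "hr_rest"),
    "hr_gain": ("hr", "hr_gain"),
    "hr_tau": ("hr", "tau"),
    "hr_noise_sd": ("hr", "hr_noise_sd"),
    "spo2_baseline": (None, "spo2_baseline"),
    "systolic_baseline": (None, "systolic_baseline"),
    "diastolic_baseline": (None, "diastolic_baseline"),
    "bp_exercise_slope": (None, "bp_exercise_slope"),
}


def read_profile(path) -> "ParticipantModel":
    """Read a flat JSON participant profile into a validated model.

    Absent keys take the documented defaults of
    :class:`legdose.device_simulator.ParticipantModel`; unknown keys and
    out-of-range values raise :class:`ValidationError`.
    """
    from .device_simulator import HRParams, ParticipantModel, ThermalParams

    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: profile must be a JSON object")

    unknown = set(raw) - set(_PROFILE_KEYS) - {"participant_id"}
    if unknown:
        raise ValidationError(f"{path}: unknown profile keys {sorted(unknown)}")

    thermal_kw, hr_kw, top_kw = {}, {}, {}
    for key, (group, attr) in _PROFILE_KEYS.items():
        if key not in raw:
            continue
        value = float(raw[key])
        if group == "thermal":
            thermal_kw[attr] = value
        elif group == "hr":
            hr_kw[attr] = value
        else:
            top_kw[attr] = value
    return ParticipantModel(
        participant_id=str(raw.get("participant_id", "unknown")),
        thermal=ThermalParams(**thermal_kw), hr=HRParams(**hr_kw), **top_kw)


def write_profile(model: "ParticipantModel", path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = {"participant_id": model.participant_id}
    for key, (group, attr) in _PROFILE_KEYS.items():
        obj = model if group is None else getattr(model, group)
        flat[key] = getattr(obj, attr)
    path.write_text(json.dumps(flat, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
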