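"""Reading, validating and writing heart-rate session records.

A *session* pairs two simultaneously worn devices: a wrist-worn PPG
sensor under test and an ECG chest-strap criterion. Each device
contributes a timestamped heart-rate series; per-session metadata
carries the participant, the activity performed and the Fitzpatrick
skin-tone score.

On disk a session directory holds ``test.csv``, ``criterion.csv`` and
``meta.json``. HR series are two-column CSV (``time_s,hr_bpm``);
timestamps may be ISO-8601 wall-clock or numeric seconds and are
normalized to seconds since the first sample at read time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Plausible human HR window (bpm, open interval); samples outside are dropped.
HR_MIN = 20.0
HR_MAX = 250.0

#: Closed activity vocabulary.
ACTIVITIES = ("badminton", "tennis", "orienteering", "run", "bike", "soccer")

#: Pooled activity groups analysed alongside single activities.
ACTIVITY_GROUPS = {
    "racket": ("badminton", "tennis"),
    "running_sports": ("orienteering", "run"),
}

DEVICE_ROLES = ("test", "criterion")


class RecordError(ValueError):
    """Raised when an HR record or metadata file violates an invariant."""


@dataclass(frozen=True)
class HRRecord:
    """One device's HR series for one session.

    Parameters
    ----------
    device_role : {"test", "criterion"}
    time : array of seconds, strictly increasing, non-negative
    hr : array of bpm values, each in the open interval (20, 250)
    native_rate_hint : samples per second of the source device, optional
    """

    device_role: str
    time: np.ndarray
    hr: np.ndarray
    native_rate_hint: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "hr", np.asarray(self.hr, dtype=float))
        if self.device_role not in DEVICE_ROLES:
            raise RecordError(f"device_role must be one of {DEVICE_ROLES}, got {self.device_role!r}")
        if self.time.ndim != 1 or self.time.shape != self.hr.shape:
            raise RecordError("time and hr must be 1-d arrays of equal length")
        if len(self.time) < 2:
            raise RecordError("an HR record needs at least 2 samples")
        if self.time[0] < 0:
            raise RecordError("timestamps must be non-negative")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise RecordError(f"timestamps must be strictly increasing; first violation after sample {i}")
        if np.any(~np.isfinite(self.hr)) or np.any(self.hr <= HR_MIN) or np.any(self.hr >= HR_MAX):
            raise RecordError(f"hr values must lie in ({HR_MIN}, {HR_MAX}) bpm")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SessionMetadata:
    session_id: str
    participant_id: str
    activity: str
    skin_tone: int
    recorded_hours: float = 0.0

    def __post_init__(self):
        if self.activity not in ACTIVITIES:
            raise RecordError(
                f"unknown activity {self.activity!r}; expected one of {sorted(ACTIVITIES)}"
            )
        if not (isinstance(self.skin_tone, (int, np.integer)) and 1 <= self.skin_tone <= 6):
            raise RecordError(f"skin_tone must be an integer in 1..6, got {self.skin_tone!r}")
        if self.recorded_hours < 0:
            raise RecordError("recorded_hours must be non-negative")


def _parse_time_column(col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Parse a timestamp column, numeric seconds or ISO-8601.

    Returns (seconds, parse_ok mask). Seconds are raw (not yet
    normalized to start at zero).
    """
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().mean() >= 0.5:
        return numeric.to_numpy(dtype=float), numeric.notna().to_numpy()
    stamps = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    ok = stamps.notna().to_numpy()
    secs = np.full(len(col), np.nan)
    if ok.any():
        ref = stamps[ok].iloc[0]
        secs[ok] = (stamps[ok] - ref).dt.total_seconds().to_numpy()
    return secs, ok


def read_hr_csv(path, device_role: str, max_bad_fraction: float = 0.05) -> HRRecord:
    """Read a two-column (timestamp, hr) CSV into a validated :class:`HRRecord`.

    Timestamps are converted to seconds from the first retained sample.
    HR values outside the plausibility window are dropped (and counted in
    the log); rows that fail to parse beyond ``max_bad_fraction`` of the
    file are a hard error, as are non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise RecordError(f"{path}: expected two columns (timestamp, hr)")
    secs, t_ok = _parse_time_column(df.iloc[:, 0])
    hr = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    parse_ok = t_ok & np.isfinite(hr)
    n_bad = int((~parse_ok).sum())
    if len(df) and n_bad / len(df) > max_bad_fraction:
        raise RecordError(
            f"{path}: {n_bad}/{len(df)} rows unparseable (> {max_bad_fraction:.0%} allowed)"
        )
    if n_bad:
        logger.warning("%s: dropped %d unparseable rows", path, n_bad)
    secs, hr = secs[parse_ok], hr[parse_ok]
    dt = np.diff(secs)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0)) + 1
        raise RecordError(f"{path}: non-monotone timestamp at row {i}")
    in_range = (hr > HR_MIN) & (hr < HR_MAX)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning("%s: dropped %d out-of-range hr samples", path, n_dropped)
    secs, hr = secs[in_range], hr[in_range]
    if len(secs) < 2:
        raise RecordError(f"{path}: fewer than 2 valid samples after cleaning")
    return HRRecord(device_role=device_role, time=secs - secs[0], hr=hr)


def write_hr_csv(record: HRRecord, path) -> Path:
    """Write a record as ``time_s,hr_bpm`` CSV at full float precision.

    ``read_hr_csv`` inverts this exactly (Python float repr round-trips).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,hr_bpm\n")
        for t, h in zip(record.time, record.hr):
            fh.write(f"{float(t)!r},{float(h)!r}\n")
    return path


def read_session_metadata(path) -> SessionMetadata:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return SessionMetadata(
            session_id=str(raw["session_id"]),
            participant_id=str(raw["participant_id"]),
            activity=raw["activity"],
            skin_tone=int(raw["skin_tone"]),
            recorded_hours=float(raw.get("recorded_hours", 0.0)),
        )
    except KeyError as exc:
        raise RecordError(f"{path}: missing metadata field {exc}") from None


def write_session_metadata(meta: SessionMetadata, path) -> Path:
    path = Path(path)
    payload = {
        "session_id": meta.session_id,
        "participant_id": meta.participant_id,
        "activity": meta.activity,
        "skin_tone": int(meta.skin_tone),
        "recorded_hours": meta.recorded_hours,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_session_dir(path) -> tuple[HRRecord, HRRecord, SessionMetadata]:
    """Load a session directory (test.csv + criterion.csv + meta.json)."""
    path = Path(path)
    test = read_hr_csv(path / "test.csv", "test")
    criterion = read_hr_csv(path / "criterion.csv", "criterion")
    meta = read_session_metadata(path / "meta.json")
    return test, criterion, meta


def summarize_sessions(metas) -> pd.DataFrame:
    """Aggregate session metadata into a per-activity descriptive table.

    Returns one row per activity with session count, total recorded
    hours and participant count, plus rows for the pooled groups and a
    grand total. Mirrors the usual "descriptive data of recorded
    sessions" table of a device-validation report.
    """
    metas = list(metas)
    if not metas:
        raise RecordError("no session metadata to summarize")
    df = pd.DataFrame(
        {
            "activity": [m.activity for m in metas],
            "participant_id": [m.participant_id for m in metas],
            "recorded_hours": [m.recorded_hours for m in metas],
        }
    )
    rows = []

    def _agg(name, sub):
        rows.append(
            {
                "stratum": name,
                "sessions": len(sub),
                "recorded_hours": float(sub["recorded_hours"].sum()),
                "participants": sub["participant_id"].nunique(),
            }
        )

    for act in ACTIVITIES:
        sub = df[df["activity"] == act]
        if len(sub):
            _agg(act, sub)
    for gname, members in ACTIVITY_GROUPS.items():
        sub = df[df["activity"].isin(members)]
        if len(sub):
            _agg(gname, sub)
    _agg("total", df)
    return pd.DataFrame(rows)
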