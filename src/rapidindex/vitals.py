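"""Per-minute vital-sign sessions: data model, I/O and clinical-validity filtering.

A monitoring session is a per-minute record of up to four channels coming
from two wireless sensors: a chest ECG patch reporting heart rate (HR,
beats/min) and respiratory rate (RR, breaths/min), and a wrist pulse
oximeter reporting oxygen saturation (SpO2, %) and pulse rate (PR,
beats/min).  Raw wireless streams contain technical noise (sensor
detachment, motion artifact), so broad physiological range filters are
applied before any modelling: a value outside its configured range is
flagged *invalid*; an absent value is *missing*, never invalid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("hr", "rr", "spo2", "pr")

#: sensor -> channels it carries
SENSOR_CHANNELS = {
    "chest_ecg": ("hr", "rr"),
    "pulse_ox": ("spo2", "pr"),
}

#: channels fed to the adaptive index (pulse rate is carried and filtered
#: but duplicates HR information and is not part of the feature vector)
INDEX_CHANNELS = ("hr", "rr", "spo2")


class SessionError(ValueError):
    """Raised for malformed or empty sessions."""


@dataclass(frozen=True)
class VitalSample:
    """One minute of vital signs. ``None`` marks a missing channel."""

    timestamp: int
    hr: float | None = None
    rr: float | None = None
    spo2: float | None = None
    pr: float | None = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.timestamp}")
        for ch in CHANNELS:
            v = getattr(self, ch)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{ch} must be finite, got {v!r}")


@dataclass(frozen=True)
class ValidityConfig:
    """Broad per-channel clinical plausibility ranges.

    Bounds are exclusive as printed on the study filters: a value is
    invalid strictly below the minimum or strictly above the maximum, so
    hr=20 and spo2=30 are valid.  Pulse rate shares the heart-rate bounds.
    """

    hr_min: float = 20.0
    hr_max: float = 300.0
    rr_min: float = 5.0
    rr_max: float = 200.0
    spo2_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("hr_min", "hr_max", "rr_min", "rr_max", "spo2_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hr_min >= self.hr_max:
            raise ValueError("hr_min must be < hr_max")
        if self.rr_min >= self.rr_max:
            raise ValueError("rr_min must be < rr_max")

    def bounds(self, channel: str) -> tuple[float, float]:
        """(low, high) bounds for a channel; +inf when unbounded above."""
        if channel in ("hr", "pr"):
            return self.hr_min, self.hr_max
        if channel == "rr":
            return self.rr_min, self.rr_max
        if channel == "spo2":
            return self.spo2_min, np.inf
        raise KeyError(channel)


@dataclass(frozen=True)
class DeteriorationEvent:
    """Annotated clinical deterioration within a session.

    ``onset_minute`` is the first escalation of therapy; ``event_minute``
    the significant deterioration itself (arrest, life-threatening event
    or unplanned intensive-care admission).
    """

    session_id: str
    onset_minute: int
    event_minute: int
    event_type: str = "unplanned_picu"

    _TYPES = ("cardiac_arrest", "respiratory_arrest", "life_threatening", "unplanned_picu")

    def __post_init__(self) -> None:
        if self.onset_minute > self.event_minute:
            raise ValueError("onset_minute must be <= event_minute")
        if self.event_type not in self._TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")


@dataclass
class MonitoringSession:
    """A per-minute multichannel vital-sign record.

    ``frame`` is indexed by integer minute (0-based, within the half-open
    intended interval) with float columns ``hr, rr, spo2, pr``; NaN marks
    a missing value.  ``validity_mask`` (set by :func:`filter_session`)
    has the same shape: True where a present value passed the range
    filter, False where it failed, NaN-irrelevant where missing.
    """

    session_id: str
    patient_age_months: float
    intended_start: int
    intended_end: int
    frame: pd.DataFrame
    validity_mask: pd.DataFrame | None = None
    annotations: list[DeteriorationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intended_end <= self.intended_start:
            raise ValueError("intended_end must be > intended_start")
        if self.patient_age_months < 0:
            raise ValueError("patient_age_months must be >= 0")
        f = self.frame
        if list(f.columns) != list(CHANNELS):
            f = f.reindex(columns=list(CHANNELS))
        if not f.index.is_monotonic_increasing:
            warnings.warn("timestamps not monotone; sorting", stacklevel=2)
            f = f.sort_index()
        if f.index.has_duplicates:
            warnings.warn("duplicate minutes; keeping last value", stacklevel=2)
            f = f[~f.index.duplicated(keep="last")]
        self.frame = f.astype(float)
        if self.validity_mask is not None and len(self.validity_mask) != len(self.frame):
            raise ValueError("validity_mask length mismatch")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        session_id: str,
        samples: Iterable[VitalSample],
        *,
        patient_age_months: float = 0.0,
        intended_start: int = 0,
        intended_end: int | None = None,
        annotations: Sequence[DeteriorationEvent] = (),
    ) -> "MonitoringSession":
        rows = {s.timestamp: [s.hr, s.rr, s.spo2, s.pr] for s in samples}
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS))
        if intended_end is None:
            intended_end = (int(frame.index.max()) + 1) if len(frame) else intended_start + 1
        return cls(
            session_id=session_id,
            patient_age_months=patient_age_months,
            intended_start=intended_start,
            intended_end=intended_end,
            frame=frame,
            annotations=list(annotations),
        )

    # -- views --------------------------------------------------------

    @property
    def samples(self) -> list[VitalSample]:
        out = []
        for t, row in self.frame.iterrows():
            vals = {ch: (None if pd.isna(row[ch]) else float(row[ch])) for ch in CHANNELS}
            out.append(VitalSample(timestamp=int(t), **vals))
        return out

    @property
    def intended_minutes(self) -> int:
        return self.intended_end - self.intended_start

    def valid_frame(self) -> pd.DataFrame:
        """Values with range-filter failures masked to NaN.

        Requires :func:`filter_session` to have run; on an unfiltered
        session the raw frame is returned unchanged.
        """
        if self.validity_mask is None:
            return self.frame.copy()
        ok = self.validity_mask.eq(True).astype(bool)
        return self.frame.where(ok | self.frame.isna())


@dataclass(frozen=True)
class SessionQualityReport:
    """Captured/valid minute accounting per sensor against intended time."""

    intended_minutes: int
    captured_minutes: dict[str, int]
    valid_minutes: dict[str, int]

    def __post_init__(self) -> None:
        for sensor in self.captured_minutes:
            if not (0 <= self.valid_minutes[sensor] <= self.captured_minutes[sensor] <= self.intended_minutes):
                raise ValueError(f"minute counts inconsistent for {sensor}")

    @property
    def proportion_captured(self) -> dict[str, float]:
        return {s: c / self.intended_minutes for s, c in self.captured_minutes.items()}

    @property
    def proportion_valid(self) -> dict[str, float]:
        return {s: v / self.intended_minutes for s, v in self.valid_minutes.items()}


# ---------------------------------------------------------------------
# operations


def validate_sample(sample: VitalSample, cfg: ValidityConfig | None = None) -> dict[str, str]:
    """Classify each channel of one sample as ``valid``/``invalid``/``missing``."""
    cfg = cfg or ValidityConfig()
    flags: dict[str, str] = {}
    for ch in CHANNELS:
        v = getattr(sample, ch)
        if v is None:
            flags[ch] = "missing"
        else:
            lo, hi = cfg.bounds(ch)
            flags[ch] = "valid" if lo <= v <= hi else "invalid"
    return flags


def _mask(frame: pd.DataFrame, cfg: ValidityConfig) -> pd.DataFrame:
    mask = pd.DataFrame(index=frame.index, columns=list(CHANNELS), dtype=object)
    for ch in CHANNELS:
        lo, hi = cfg.bounds(ch)
        col = frame[ch]
        vals = ((col >= lo) & (col <= hi)).to_numpy(dtype=object)
        vals[col.isna().to_numpy()] = np.nan
        mask[ch] = vals
    return mask


def filter_session(
    session: MonitoringSession, cfg: ValidityConfig | None = None
) -> tuple[MonitoringSession, SessionQualityReport]:
    """Apply range filters; return the masked session and its quality report.

    A sensor-minute is *captured* when at least one of its channels is
    present, *valid* when captured and no present channel fails its
    range.  Filtering is idempotent and never alters stored values.
    """
    cfg = cfg or ValidityConfig()
    if session.frame.empty:
        raise SessionError(f"session {session.session_id!r} has no data")
    in_window = (session.frame.index >= session.intended_start) & (
        session.frame.index < session.intended_end
    )
    frame = session.frame.loc[in_window]
    mask = _mask(frame, cfg)

    captured: dict[str, int] = {}
    valid: dict[str, int] = {}
    for sensor, chans in SENSOR_CHANNELS.items():
        present = frame[list(chans)].notna()
        cap = present.any(axis=1)
        bad = pd.DataFrame({c: mask[c].eq(False) for c in chans}).any(axis=1)
        captured[sensor] = int(cap.sum())
        valid[sensor] = int((cap & ~bad).sum())

    report = SessionQualityReport(
        intended_minutes=session.intended_minutes,
        captured_minutes=captured,
        valid_minutes=valid,
    )
    full_mask = _mask(session.frame, cfg)
    return replace(session, validity_mask=full_mask), report


# ---------------------------------------------------------------------
# I/O

_META_FIELDS = ("session_id", "patient_age_months", "intended_start", "intended_end")


def write_session(session: MonitoringSession, path: str | Path, format: str | None = None) -> None:
    """Write a session to CSV (commented metadata header) or JSON."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        with open(path, "w") as fh:
            for k in _META_FIELDS:
                fh.write(f"# {k}={getattr(session, k)}\n")
            frame = session.frame.rename_axis("minute").reset_index()
            frame.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {k: getattr(session, k) for k in _META_FIELDS}
        payload["samples"] = [
            {"minute": int(t), **{ch: (None if pd.isna(v) else v) for ch, v in row.items()}}
            for t, row in session.frame.iterrows()
        ]
        payload["annotations"] = [
            {
                "session_id": e.session_id,
                "onset_minute": e.onset_minute,
                "event_minute": e.event_minute,
                "event_type": e.event_type,
            }
            for e in session.annotations
        ]
        Path(path).write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_session(path: str | Path, format: str | None = None) -> MonitoringSession:
    """Read a session written by :func:`write_session`.

    CSV columns are ``minute,hr,rr,spo2,pr`` with empty cells for missing
    values; unknown columns are ignored with a warning; a missing channel
    column yields an entirely-missing channel; malformed rows raise a
    :class:`SessionError` naming the row.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(payload["samples"]).set_index("minute")
        frame = frame.reindex(columns=list(CHANNELS))
        annotations = [DeteriorationEvent(**a) for a in payload.get("annotations", [])]
        return MonitoringSession(
            session_id=str(payload["session_id"]),
            patient_age_months=float(payload["patient_age_months"]),
            intended_start=int(payload["intended_start"]),
            intended_end=int(payload["intended_end"]),
            frame=frame,
            annotations=annotations,
        )
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        k, _, v = line.lstrip("# ").rstrip("\n").partition("=")
        meta[k] = v

    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])))
    if "minute" not in table.columns:
        raise SessionError(f"{path}: no 'minute' column")
    unknown = [c for c in table.columns if c not in ("minute", *CHANNELS)]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown}", stacklevel=2)
        table = table.drop(columns=unknown)
    bad = table["minute"].isna() | (table["minute"] % 1 != 0) | (table["minute"] < 0)
    if bad.any():
        raise SessionError(f"{path}: malformed row {int(bad.idxmax()) + 1}")
    frame = table.set_index(table["minute"].astype(int)).drop(columns="minute")
    frame = frame.reindex(columns=list(CHANNELS))
    return MonitoringSession(
        session_id=meta.get("session_id", path.stem),
        patient_age_months=float(meta.get("patient_age_months", 0)),
        intended_start=int(meta.get("intended_start", 0)),
        intended_end=int(meta.get("intended_end", frame.index.max() + 1 if len(frame) else 1)),
        frame=frame,
    )
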