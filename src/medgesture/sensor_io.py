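"""Reading, writing and rate-standardising tri-axial wrist accelerometer logs.

A recording session is a CSV of timestamped x, y, z acceleration samples
logged by a smartwatch, nominally at 25 Hz.  Timestamps are stored internally
as integer epoch milliseconds; acceleration units are treated as opaque but
consistent across datasets (the logging hardware does not declare whether
values are m/s^2 or g, nor whether gravity is included).

Alongside each sensor log, participants self-report activity events in an
annotation CSV of (participant, activity, protocol, start, end) intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MalformedInputError, SchemaError

logger = logging.getLogger(__name__)

#: Fixed ordering of the four activity classes; used for one-hot encoding
#: and deterministic tie-breaking throughout the pipeline.
CLASS_ORDER = ("medication", "eating", "smoking", "jogging")

PROTOCOLS = ("natural", "scripted", "n/a")

ISO_MS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


@dataclass(frozen=True)
class Dialect:
    """Column mapping and timestamp format for a sensor CSV flavour."""

    timestamp_col: str = "timestamp"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    time_format: str = ISO_MS_FORMAT

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            block = yaml.safe_load(fh) or {}
        known = {k: v for k, v in block.items() if k in cls.__dataclass_fields__}
        return cls(**known)


DEFAULT_DIALECT = Dialect()


@dataclass(eq=False)
class SensorLog:
    """One recording session: ordered timestamped tri-axial acceleration.

    Attributes
    ----------
    participant_id:
        Opaque identifier of the wearer.
    time_ms:
        int64 array of epoch milliseconds, nondecreasing.
    xyz:
        float64 array of shape (n, 3); columns are the x, y, z axes.
    nominal_rate:
        Sampling rate in Hz the log is believed to follow (25 after
        standardisation).
    """

    participant_id: str
    time_ms: np.ndarray
    xyz: np.ndarray
    nominal_rate: float = 25.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ConfigurationError("xyz must have shape (n, 3)")
        if self.time_ms.shape[0] != self.xyz.shape[0]:
            raise ConfigurationError("time_ms and xyz lengths differ")
        if len(self.time_ms) > 1 and np.any(np.diff(self.time_ms) < 0):
            raise ConfigurationError("timestamps must be nondecreasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ConfigurationError("acceleration values must be finite")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.time_ms[-1] - self.time_ms[0]) / 1000.0


@dataclass(frozen=True)
class AnnotationRecord:
    """A self-reported activity event interval."""

    participant_id: str
    activity: str
    protocol: str
    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if self.activity not in CLASS_ORDER:
            raise SchemaError(
                f"unknown activity {self.activity!r}; allowed: {list(CLASS_ORDER)}"
            )
        if self.protocol not in PROTOCOLS:
            raise SchemaError(
                f"unknown protocol {self.protocol!r}; allowed: {list(PROTOCOLS)}"
            )
        if self.start_ms >= self.end_ms:
            raise ConfigurationError("annotation start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


def _parse_times(series: pd.Series, time_format: str, path) -> np.ndarray:
    parsed = pd.to_datetime(series, format=time_format, errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        # +2: 1 for the header row, 1 for 1-based line numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise MalformedInputError(
            f"{path}: unparseable timestamp {series.iloc[line - 2]!r} at line {line}"
        )
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise MalformedInputError(f"{path}: missing timestamp at line {line}")
    return (parsed.astype("int64") // 1_000_000).to_numpy()


def read_sensor_csv(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    participant_id: str = "",
) -> SensorLog:
    """Read a sensor CSV into a :class:`SensorLog`.

    Rows are sorted by timestamp (stable sort, so file order breaks ties);
    duplicate timestamps are collapsed keeping the first occurrence.  Row and
    drop counts are logged.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    needed = [dialect.timestamp_col, dialect.x_col, dialect.y_col, dialect.z_col]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")
    time_ms = _parse_times(frame[dialect.timestamp_col], dialect.time_format, path)
    xyz = frame[[dialect.x_col, dialect.y_col, dialect.z_col]].to_numpy(dtype=np.float64)

    order = np.argsort(time_ms, kind="stable")
    time_ms, xyz = time_ms[order], xyz[order]
    keep = np.ones(len(time_ms), dtype=bool)
    keep[1:] = np.diff(time_ms) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d duplicate-timestamp rows", path, dropped)
    logger.info("%s: read %d rows (%d kept)", path, len(frame), int(keep.sum()))
    return SensorLog(participant_id, time_ms[keep], xyz[keep], nominal_rate=float("nan"))


def write_sensor_csv(log: SensorLog, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write a log as CSV readable by :func:`read_sensor_csv`.

    Acceleration values are written with 17 significant digits so the
    read/write round trip preserves IEEE doubles bit-exactly.
    """
    if len(log) == 0:
        raise ConfigurationError("refusing to write an empty sensor log")
    stamps = pd.to_datetime(log.time_ms, unit="ms").strftime("%Y-%m-%dT%H:%M:%S.%f")
    stamps = [s[:-3] for s in stamps]  # microseconds -> milliseconds
    frame = pd.DataFrame(
        {
            dialect.timestamp_col: stamps,
            dialect.x_col: log.xyz[:, 0],
            dialect.y_col: log.xyz[:, 1],
            dialect.z_col: log.xyz[:, 2],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_annotations(path) -> list[AnnotationRecord]:
    """Read an annotation CSV; returns records sorted by start time.

    Records with start >= end are rejected and counted in the log output
    rather than raising, since self-reports are known to contain slips.
    """
    # keep_default_na: the literal protocol value "n/a" must survive parsing
    frame = pd.read_csv(path, keep_default_na=False)
    needed = ["participant_id", "activity", "protocol", "start", "end"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    unknown = set(frame["activity"]) - set(CLASS_ORDER)
    if unknown:
        raise SchemaError(
            f"{path}: unknown activity label(s) {sorted(unknown)}; "
            f"allowed: {list(CLASS_ORDER)}"
        )
    start = _parse_times(frame["start"], ISO_MS_FORMAT, path)
    end = _parse_times(frame["end"], ISO_MS_FORMAT, path)
    records, rejected = [], 0
    for i in range(len(frame)):
        if start[i] >= end[i]:
            rejected += 1
            continue
        records.append(
            AnnotationRecord(
                participant_id=str(frame["participant_id"].iloc[i]),
                activity=str(frame["activity"].iloc[i]),
                protocol=str(frame["protocol"].iloc[i]),
                start_ms=int(start[i]),
                end_ms=int(end[i]),
            )
        )
    if rejected:
        logger.warning("%s: rejected %d records with start >= end", path, rejected)
    records.sort(key=lambda r: r.start_ms)
    return records


def write_annotations(records, path) -> None:
    """Inverse of :func:`read_annotations` (same header and time format)."""
    fmt = lambda ms: pd.Timestamp(ms, unit="ms").strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3]
    frame = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "activity": [r.activity for r in records],
            "protocol": [r.protocol for r in records],
            "start": [fmt(r.start_ms) for r in records],
            "end": [fmt(r.end_ms) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def standardize_rate(log: SensorLog, target_rate: float = 25.0) -> SensorLog:
    """Resample a log onto a uniform grid at ``target_rate`` Hz.

    Oversampled input (native rate above target) is decimated: each grid
    point takes the nearest *preceding* raw sample, so no values are
    fabricated when discarding data.  Undersampled input is linearly
    interpolated per axis.  Total duration is preserved to within one output
    sample period.
    """
    if target_rate <= 0:
        raise ConfigurationError("target_rate must be positive")
    if len(log) < 2:
        raise ConfigurationError("log too short to resample (need >= 2 samples)")
    duration_ms = int(log.time_ms[-1] - log.time_ms[0])
    period_ms = 1000.0 / target_rate
    if duration_ms < period_ms:
        raise ConfigurationError("log shorter than one output sample period")
    n_out = int(np.floor(duration_ms / period_ms)) + 1
    grid_ms = log.time_ms[0] + np.round(np.arange(n_out) * period_ms).astype(np.int64)

    native_rate = 1000.0 * (len(log) - 1) / duration_ms
    if native_rate >= target_rate:  # decimate onto the grid
        idx = np.searchsorted(log.time_ms, grid_ms, side="right") - 1
        xyz = log.xyz[idx]
    else:  # interpolate per axis
        xyz = np.column_stack(
            [np.interp(grid_ms, log.time_ms, log.xyz[:, k]) for k in range(3)]
        )
    return replace(log, time_ms=grid_ms, xyz=xyz, nominal_rate=target_rate)
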