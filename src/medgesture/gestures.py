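"""Gesture extraction, duration statistics and outlier validation.

Self-reported event intervals are cut out of the standardized sensor log as
closed-interval segments.  Durations are screened against the study's outlier
bounds — a gesture lasting <= 8 s is implausibly short for a complete
medication-taking sequence (users double-tapping start/stop), while >= 100 s
usually means several events were reported as one, or unrelated activity was
included.  Two automated corrections operationalise what a human supervisor
would do with upper outliers: splitting a recording at sustained quiet runs,
and trimming quiet padding off the ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, EmptyInputError
from .sensor_io import AnnotationRecord, SensorLog

logger = logging.getLogger(__name__)

VALID = "valid"
LOWER_OUTLIER = "lower_outlier"
UPPER_OUTLIER = "upper_outlier"
INVALID = "invalid"
CORRECTED = "corrected"
VALIDITIES = (VALID, LOWER_OUTLIER, UPPER_OUTLIER, INVALID, CORRECTED)

#: Study outlier bounds in seconds.
LOWER_BOUND_S = 8.0
UPPER_BOUND_S = 100.0


@dataclass(eq=False)
class Gesture:
    """A validated sensor segment for one self-reported event.

    ``source_id`` identifies the originating annotation (plus a suffix for
    split children); it is what the leakage-safe dataset split groups on.
    """

    participant_id: str
    activity: str
    protocol: str
    time_ms: np.ndarray
    xyz: np.ndarray
    validity: str = VALID
    source_id: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if self.validity not in VALIDITIES:
            raise ConfigurationError(f"unknown validity {self.validity!r}")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def duration_s(self) -> float:
        """Elapsed seconds between first and last sample (0 if < 2 samples)."""
        if len(self) < 2:
            return 0.0
        return float(self.time_ms[-1] - self.time_ms[0]) / 1000.0


@dataclass(frozen=True)
class DurationStats:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


def extract_gestures(
    log: SensorLog, annotations: list[AnnotationRecord]
) -> list[Gesture]:
    """Cut one gesture segment per annotation out of a standardized log.

    The segment is the closed interval start <= t <= end.  An annotation with
    no overlapping samples yields an empty segment marked invalid rather than
    an error, so bookkeeping stays one-to-one with the self reports.
    """
    out = []
    for k, ann in enumerate(annotations):
        lo = np.searchsorted(log.time_ms, ann.start_ms, side="left")
        hi = np.searchsorted(log.time_ms, ann.end_ms, side="right")
        seg_t, seg_xyz = log.time_ms[lo:hi], log.xyz[lo:hi]
        out.append(
            Gesture(
                participant_id=ann.participant_id,
                activity=ann.activity,
                protocol=ann.protocol,
                time_ms=seg_t,
                xyz=seg_xyz,
                validity=VALID if len(seg_t) else INVALID,
                source_id=f"{ann.participant_id}:{ann.start_ms}:{k}",
            )
        )
    return out


def duration_stats(gestures, protocol_filter: str | None = None) -> DurationStats:
    """Summary statistics of gesture durations (sample SD, n-1 denominator)."""
    if protocol_filter is not None:
        gestures = [g for g in gestures if g.protocol == protocol_filter]
    if not gestures:
        raise EmptyInputError("no gestures after protocol filtering")
    d = np.array([g.duration_s for g in gestures])
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return DurationStats(
        n=len(d),
        mean=float(np.mean(d)),
        sd=sd,
        median=float(np.median(d)),
        min=float(np.min(d)),
        max=float(np.max(d)),
    )


def flag_outliers(
    gestures,
    lower_s: float = LOWER_BOUND_S,
    upper_s: float = UPPER_BOUND_S,
) -> list[Gesture]:
    """Set validity from duration thresholds (<= lower_s / >= upper_s).

    Gestures already marked invalid (empty segments) keep that mark.
    """
    if lower_s >= upper_s:
        raise ConfigurationError("lower_s must be < upper_s")
    out = []
    counts = dict.fromkeys(VALIDITIES, 0)
    for g in gestures:
        if g.validity == INVALID:
            v = INVALID
        elif g.duration_s <= lower_s:
            v = LOWER_OUTLIER
        elif g.duration_s >= upper_s:
            v = UPPER_OUTLIER
        else:
            v = VALID
        counts[v] += 1
        out.append(replace(g, validity=v))
    logger.info("outlier screening: %s", {k: v for k, v in counts.items() if v})
    return out


def _quiet_mask(
    xyz: np.ndarray, quiet_threshold: float | None, local_window: int = 25
) -> np.ndarray:
    """Per-sample stillness flag from acceleration magnitude.

    A resting wrist reads a steady magnitude (gravity), so a sample is
    "quiet" when the magnitude deviates little from its local (~1 s rolling)
    median; active motion makes the magnitude fluctuate rapidly.  When no
    absolute threshold is given it defaults to 5% of the segment's magnitude
    interquartile range, so "quiet" scales with how energetic the segment is.
    """
    import pandas as pd

    mag = np.linalg.norm(xyz, axis=1)
    if quiet_threshold is None:
        q1, q3 = np.percentile(mag, [25, 75])
        quiet_threshold = 0.05 * (q3 - q1)
    local_median = (
        pd.Series(mag).rolling(local_window, center=True, min_periods=1).median()
    )
    return np.abs(mag - local_median.to_numpy()) < quiet_threshold


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def split_multi_event(
    gesture: Gesture,
    min_gap_s: float = 5.0,
    quiet_threshold: float | None = None,
) -> list[Gesture]:
    """Split an upper-outlier recording at sustained quiet runs.

    Several consecutively-performed events reported as one annotation show up
    as activity bursts separated by near-still intervals.  Each maximal quiet
    run at least ``min_gap_s`` long becomes a cut point (at its midpoint);
    children are marked corrected and concatenate exactly back to the parent.
    A segment with no qualifying gap is returned unchanged.
    """
    if len(gesture) < 2:
        return [gesture]
    rate = 1000.0 * (len(gesture) - 1) / (gesture.time_ms[-1] - gesture.time_ms[0])
    min_run = max(1, int(round(min_gap_s * rate)))
    quiet = _quiet_mask(gesture.xyz, quiet_threshold)
    # Interior gaps only: a leading/trailing quiet run is trimming's job.
    cuts = [
        (a + b) // 2
        for a, b in _runs(quiet)
        if (b - a) >= min_run and a > 0 and b < len(gesture)
    ]
    if not cuts:
        return [gesture]
    bounds = [0, *cuts, len(gesture)]
    children = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        children.append(
            replace(
                gesture,
                time_ms=gesture.time_ms[a:b],
                xyz=gesture.xyz[a:b],
                validity=CORRECTED,
                source_id=f"{gesture.source_id}/{i}",
            )
        )
    return children


def trim_gesture(gesture: Gesture, quiet_threshold: float | None = None) -> Gesture:
    """Remove leading/trailing quiet runs; mark the result corrected.

    Trimming repeats until both ends are active in the trimmed segment's own
    context (the local-median mask shifts once neighbours are removed), so
    the operation is a fixed point: trimming a trimmed gesture is a no-op.
    A fully quiet segment carries no gesture and is marked invalid.
    """
    current = gesture
    while True:
        if len(current) == 0:
            return replace(current, validity=INVALID)
        quiet = _quiet_mask(current.xyz, quiet_threshold)
        active = np.flatnonzero(~quiet)
        if len(active) == 0:
            return replace(current, validity=INVALID)
        a, b = int(active[0]), int(active[-1]) + 1
        if a == 0 and b == len(current):
            return current
        current = replace(
            current,
            time_ms=current.time_ms[a:b],
            xyz=current.xyz[a:b],
            validity=CORRECTED,
        )


def validation_report(gestures) -> "pd.DataFrame":
    """Per-gesture audit table: participant, activity, duration, validity."""
    import pandas as pd

    actions = {
        VALID: "kept",
        CORRECTED: "kept (corrected)",
        LOWER_OUTLIER: "discarded (too short)",
        UPPER_OUTLIER: "needs correction",
        INVALID: "discarded (no signal)",
    }
    return pd.DataFrame(
        {
            "participant_id": [g.participant_id for g in gestures],
            "activity": [g.activity for g in gestures],
            "protocol": [g.protocol for g in gestures],
            "duration_s": [g.duration_s for g in gestures],
            "validity": [g.validity for g in gestures],
            "action": [actions[g.validity] for g in gestures],
        }
    )
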