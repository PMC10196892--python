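"""Synthetic tri-axial accelerometer sessions with the study's structure.

No public recordings of the medication-taking study exist, so this module
generates sessions that exercise every pipeline stage: 28 participants, 10
gestures per day for 5 days per protocol (2800 gestures at defaults), with
sensor CSVs and self-report annotation CSVs in the formats sensor_io reads.

Each complex activity is a grammar over mini-activities rendered as
piecewise-smooth waveform primitives (ramps, raised-cosine bumps,
oscillation bursts):

* medication taking — open-bottle, dispense, hand-to-mouth, pill-into-mouth,
  hand-off-mouth, pick-up-water, drink-water, lower-cup, close-bottle; the
  drinking phase carries the hallmark gradual y-axis rise.  Scripted events
  use the fixed order; natural events interleave the sub-chains randomly
  while preserving physical ordering (you cannot drink before picking up
  the cup).
* eating — repeated bite motifs; smoking — repeated puff motifs;
  jogging — quasi-periodic strides near 2.5 Hz.

Event durations are lognormal, moment-matched per protocol to the study's
natural (mean 18.47 s, SD 14.34 s) and scripted (mean 20.11 s, SD 20.65 s)
statistics.  Amplitude units are arbitrary but consistent.  A configurable
fraction of *annotations* is deliberately corrupted (too-short marks,
several events merged into one record) to exercise the validation stage;
the underlying gestures always follow the duration model.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigurationError
from .gestures import Gesture
from .sensor_io import (
    AnnotationRecord,
    SensorLog,
    write_annotations,
    write_sensor_csv,
)

#: Natural / scripted duration statistics (seconds) the lognormal model is
#: moment-matched to.
DURATION_STATS = {
    "natural": (18.47, 14.34),
    "scripted": (20.11, 20.65),
    # invented scales for the secondary activities (no published statistics)
    "eating": (25.0, 8.0),
    "smoking": (30.0, 10.0),
    "jogging": (45.0, 15.0),
}

STRIDE_FREQUENCY_HZ = 2.5

#: Static wrist-orientation (gravity) component per activity.  Holding a
#: pill bottle / cup, a cigarette, food, or swinging the arm while jogging
#: each put the watch in a characteristic attitude, so the constant
#: gravity projection differs between activities; this is a large part of
#: what makes the four classes separable from a wrist-worn accelerometer.
ORIENTATION = {
    "medication": np.array([0.0, 0.3, 0.35]),
    "eating": np.array([0.35, -0.25, 0.15]),
    "smoking": np.array([-0.35, 0.15, 0.3]),
    "jogging": np.array([0.0, -0.35, -0.2]),
}

#: Scripted medication mini-activity order; natural events interleave the
#: three sub-chains (bottle, pill, water) preserving intra-chain order.
MEDICATION_CHAINS = (
    ("open_bottle", "dispense"),
    ("hand_to_mouth", "pill_into_mouth", "hand_off_mouth"),
    ("pick_up_water", "drink_water", "lower_cup", "close_bottle"),
)
SCRIPTED_SEQUENCE = tuple(m for chain in MEDICATION_CHAINS for m in chain)

#: Base (unscaled) duration in seconds per mini-activity.
BASE_DURATION = {
    "open_bottle": 2.0,
    "dispense": 1.5,
    "hand_to_mouth": 1.5,
    "pill_into_mouth": 1.0,
    "hand_off_mouth": 1.5,
    "pick_up_water": 1.5,
    "drink_water": 5.0,
    "lower_cup": 1.5,
    "close_bottle": 2.0,
    "puff": 3.0,
    "bite": 2.0,
    "stride": 0.4,
    "idle": 1.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-structure and signal parameters of the simulator."""

    participants: int = 28
    gestures_per_day: int = 10
    days: int = 5
    protocols: tuple = ("natural", "scripted")
    sample_rate: float = 25.0
    noise_sd: float = 0.05
    participant_variability: float = 0.1
    idle_mean_s: float = 60.0
    frac_too_short: float = 0.03
    frac_multi_event: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.participants, self.gestures_per_day, self.days) <= 0:
            raise ConfigurationError("participant/day/gesture counts must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        for p in self.protocols:
            if p not in ("natural", "scripted"):
                raise ConfigurationError(f"unknown protocol {p!r}")


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-wearer amplitude scale and baseline offset jitter."""

    scale: np.ndarray
    offset: np.ndarray

    @classmethod
    def draw(cls, rng, variability: float) -> "ParticipantProfile":
        return cls(
            scale=1.0 + variability * rng.standard_normal(3),
            offset=variability * rng.standard_normal(3),
        )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal matching the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def sample_durations(protocol: str, n: int, rng) -> np.ndarray:
    """Draw n event durations (seconds) from the protocol's lognormal model."""
    mean, sd = DURATION_STATS[protocol]
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# waveform primitives


def _bump(n: int) -> np.ndarray:
    """Raised-cosine envelope 0 -> 1 -> 0 over n samples."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _ramp(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def _wiggle(n: int, rate: float, freq: float) -> np.ndarray:
    t = np.arange(n) / rate
    return np.sin(2.0 * np.pi * freq * t) * _bump(n)


def _mini_waveform(name: str, n: int, rate: float) -> np.ndarray:
    """Noise-free (n, 3) template for one mini-activity."""
    out = np.zeros((n, 3))
    if name == "open_bottle":
        out[:, 0] = 0.6 * _wiggle(n, rate, 1.5)
        out[:, 2] = 0.3 * _wiggle(n, rate, 1.5)
    elif name == "dispense":
        out[:, 0] = 0.8 * _bump(n)
    elif name == "hand_to_mouth":
        out[:, 2] = 0.9 * _ramp(n)
        out[:, 0] = 0.3 * _bump(n)
    elif name == "pill_into_mouth":
        out[:, 2] = 0.9
        out[:, 0] = 0.4 * _bump(n)
    elif name == "hand_off_mouth":
        out[:, 2] = 0.9 * _ramp(n)[::-1]
    elif name == "pick_up_water":
        out[:, 0] = 0.7 * _bump(n)
        out[:, 1] = 0.3 * _ramp(n)
    elif name == "drink_water":
        # hallmark of the medication event: gradual y-axis rise into a hold
        k = max(1, n // 3)
        out[:k, 1] = 0.3 + 0.9 * _ramp(k)
        out[k:, 1] = 1.2
        out[:, 2] = 0.4
    elif name == "lower_cup":
        out[:, 1] = 1.2 * _ramp(n)[::-1]
    elif name == "close_bottle":
        out[:, 0] = 0.5 * _wiggle(n, rate, 2.0)
        out[:, 2] = 0.25 * _wiggle(n, rate, 2.0)
    elif name == "puff":
        out[:, 2] = 1.0 * _bump(n)
        out[:, 1] = 0.25 * _bump(n)
    elif name == "bite":
        out[:, 0] = 1.0 * _bump(n)
        out[:, 1] = 0.5 * _bump(n)
    elif name == "stride":
        t = np.arange(n) / rate
        out[:, 0] = 1.2 * np.sin(2.0 * np.pi * STRIDE_FREQUENCY_HZ * t)
        out[:, 1] = 0.9 * np.sin(2.0 * np.pi * STRIDE_FREQUENCY_HZ * t + np.pi / 2)
        out[:, 2] = 0.7 * np.sin(2.0 * np.pi * 2 * STRIDE_FREQUENCY_HZ * t)
    elif name == "idle":
        pass
    else:
        raise ConfigurationError(f"no waveform grammar for mini-activity {name!r}")
    return out


def _interleave_chains(rng) -> list[str]:
    """Random merge of the medication sub-chains preserving intra-chain order
    (a natural-protocol sequence).  The event always starts by opening the
    bottle."""
    chains = [list(c) for c in MEDICATION_CHAINS]
    seq = [chains[0].pop(0)]  # open_bottle first
    while any(chains):
        nonempty = [i for i, c in enumerate(chains) if c]
        pick = nonempty[rng.integers(len(nonempty))]
        seq.append(chains[pick].pop(0))
    return seq


def mini_sequence(activity: str, protocol: str, duration_s: float, rng) -> list[tuple[str, float]]:
    """(mini-activity, seconds) schedule for one event of the target length."""
    if activity == "medication":
        names = (
            list(SCRIPTED_SEQUENCE)
            if protocol == "scripted"
            else _interleave_chains(rng)
        )
    elif activity == "eating":
        n = max(1, int(round(duration_s / BASE_DURATION["bite"] / 2)))
        names = [m for _ in range(n) for m in ("bite", "idle")][:-1]
    elif activity == "smoking":
        n = max(1, int(round(duration_s / BASE_DURATION["puff"] / 2)))
        names = [m for _ in range(n) for m in ("puff", "idle")][:-1]
    elif activity == "jogging":
        names = ["stride"]
    else:
        raise ConfigurationError(f"no grammar for activity {activity!r}")
    base = np.array([BASE_DURATION[m] for m in names])
    if activity == "jogging":
        base = np.array([duration_s])
    scaled = base * (duration_s / base.sum())
    return list(zip(names, scaled))


def synthesize_waveform(
    activity: str,
    protocol: str,
    duration_s: float,
    rate: float,
    rng,
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Noise-free event waveform plus per-phase sample boundaries.

    Returns (xyz of shape (n, 3), [(mini_name, start_idx, stop_idx), ...]).
    """
    schedule = mini_sequence(activity, protocol, duration_s, rng)
    chunks, phases, pos = [], [], 0
    for name, secs in schedule:
        n = max(2, int(round(secs * rate)))
        chunks.append(_mini_waveform(name, n, rate))
        phases.append((name, pos, pos + n))
        pos += n
    return np.concatenate(chunks) + ORIENTATION[activity], phases


def simulate_gesture(
    activity: str,
    protocol: str,
    profile: ParticipantProfile,
    rng,
    config: SimConfig = SimConfig(),
    duration_s: float | None = None,
    start_ms: int = 0,
    participant_id: str = "P00",
    source_id: str = "",
) -> Gesture:
    """One labeled synthetic event with participant jitter and sensor noise."""
    if activity not in ORIENTATION:
        raise ConfigurationError(f"no waveform grammar for activity {activity!r}")
    if duration_s is None:
        key = protocol if activity == "medication" else activity
        duration_s = float(sample_durations(key, 1, rng)[0])
    xyz, _ = synthesize_waveform(activity, protocol, duration_s, config.sample_rate, rng)
    xyz = xyz * profile.scale + profile.offset
    if config.noise_sd > 0:
        xyz = xyz + config.noise_sd * rng.standard_normal(xyz.shape)
    period_ms = 1000.0 / config.sample_rate
    time_ms = start_ms + np.round(np.arange(len(xyz)) * period_ms).astype(np.int64)
    return Gesture(
        participant_id=participant_id,
        activity=activity,
        protocol=protocol,
        time_ms=time_ms,
        xyz=xyz,
        source_id=source_id or f"sim:{participant_id}:{activity}:{start_ms}",
    )


# ---------------------------------------------------------------------------
# full-study simulation


@dataclass
class SessionPlan:
    """One participant-day recording: gestures plus annotation records."""

    participant_id: str
    day: int
    protocol: str
    gestures: list[Gesture]
    annotations: list[AnnotationRecord]


@dataclass
class StudyPlan:
    sessions: list[SessionPlan]
    config: SimConfig

    @property
    def gestures(self) -> list[Gesture]:
        return [g for s in self.sessions for g in s.gestures]

    def durations(self, protocol: str | None = None) -> np.ndarray:
        gs = self.gestures
        if protocol is not None:
            gs = [g for g in gs if g.protocol == protocol]
        return np.array([g.duration_s for g in gs])


def plan_study(config: SimConfig = SimConfig()) -> StudyPlan:
    """Lay out every session: waveforms, idle gaps and (possibly corrupted)
    annotation records.  Deterministic for a fixed config seed.

    Corruptions affect only the annotation records: a "too short" record
    marks a sub-interval under 8 s of a normal event; a "multi event" record
    merges an event's record into its predecessor, reproducing several
    consecutively-taken medications reported as one.
    """
    root_ss = np.random.SeedSequence(config.seed)
    sessions = []
    day_blocks = [(p, d) for p in config.protocols for d in range(1, config.days + 1)]
    for p_idx in range(config.participants):
        pid = f"P{p_idx + 1:02d}"
        p_rng = np.random.default_rng(root_ss.spawn(1)[0])
        profile = ParticipantProfile.draw(p_rng, config.participant_variability)
        for block_idx, (protocol, day) in enumerate(day_blocks):
            rng = p_rng
            t_ms = 0
            gestures, annotations = [], []
            day_number = block_idx + 1
            for k in range(config.gestures_per_day):
                t_ms += int(round(1000 * rng.exponential(config.idle_mean_s))) + 1000
                g = simulate_gesture(
                    "medication", protocol, profile, rng, config,
                    start_ms=t_ms, participant_id=pid,
                    source_id=f"{pid}:d{day_number}:g{k}",
                )
                start, end = int(g.time_ms[0]), int(g.time_ms[-1])
                u = rng.uniform()
                if u < config.frac_too_short and g.duration_s > 8.0:
                    short = rng.uniform(1.0, 7.0)
                    ann = AnnotationRecord(pid, "medication", protocol,
                                           start, start + int(short * 1000))
                elif (
                    u < config.frac_too_short + config.frac_multi_event
                    and annotations
                ):
                    prev = annotations.pop()
                    ann = AnnotationRecord(pid, "medication", protocol,
                                           prev.start_ms, end)
                else:
                    ann = AnnotationRecord(pid, "medication", protocol, start, end)
                gestures.append(g)
                annotations.append(ann)
                t_ms = end
            sessions.append(SessionPlan(pid, day_number, protocol, gestures, annotations))
    return StudyPlan(sessions=sessions, config=config)


def _session_log(session: SessionPlan, config: SimConfig, rng) -> SensorLog:
    """Concatenate a session's gestures with idle (noise-only) filler so the
    annotation intervals cover exactly the non-idle segments."""
    period_ms = 1000.0 / config.sample_rate
    times, values = [], []
    cursor = 0
    for g in session.gestures:
        gap_n = int((g.time_ms[0] - cursor) / period_ms)
        if gap_n > 0:
            gap_t = cursor + np.round(np.arange(gap_n) * period_ms).astype(np.int64)
            gap_v = config.noise_sd * rng.standard_normal((gap_n, 3))
            keep = gap_t < g.time_ms[0]
            times.append(gap_t[keep])
            values.append(gap_v[keep])
        times.append(g.time_ms)
        values.append(g.xyz)
        cursor = int(g.time_ms[-1]) + int(period_ms)
    return SensorLog(
        participant_id=session.participant_id,
        time_ms=np.concatenate(times),
        xyz=np.concatenate(values),
        nominal_rate=config.sample_rate,
    )


def simulate_study(config: SimConfig = SimConfig(), out_dir=None) -> StudyPlan:
    """Generate the full study; optionally write one sensor CSV and one
    annotation CSV per participant-day plus a YAML manifest to ``out_dir``.
    """
    plan = plan_study(config)
    if out_dir is None:
        return plan
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))
    files = []
    activity_counts: dict[str, int] = {}
    sample_counts: dict[str, int] = {}
    for s in plan.sessions:
        stem = f"{s.participant_id}_day{s.day:02d}_{s.protocol}"
        log = _session_log(s, config, rng)
        write_sensor_csv(log, out / f"{stem}_sensor.csv")
        write_annotations(s.annotations, out / f"{stem}_annotations.csv")
        files.append(stem)
        for g in s.gestures:
            activity_counts[g.activity] = activity_counts.get(g.activity, 0) + 1
            sample_counts[g.activity] = sample_counts.get(g.activity, 0) + len(g)
    manifest = {
        "seed": config.seed,
        "files": files,
        "gesture_counts": activity_counts,
        "sample_counts": sample_counts,
        "total_gestures": sum(activity_counts.values()),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return plan


def simulate_secondary_sets(
    config: SimConfig = SimConfig(),
    counts: dict[str, int] | None = None,
) -> dict[str, list[Gesture]]:
    """Labeled eating / smoking / jogging gesture collections.

    Default counts are a deliberate ~1:100 scale-down of the secondary
    datasets' gesture totals; the waveforms are synthetic stand-ins, not the
    original recordings.
    """
    if counts is None:
        counts = {"eating": 54, "smoking": 13, "jogging": 59}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EC]))
    out: dict[str, list[Gesture]] = {}
    for activity in sorted(counts):
        gestures = []
        for k in range(counts[activity]):
            profile = ParticipantProfile.draw(rng, config.participant_variability)
            gestures.append(
                simulate_gesture(
                    activity, "n/a", profile, rng, config,
                    participant_id=f"S_{activity}_{k:04d}",
                    source_id=f"sec:{activity}:{k}",
                )
            )
        out[activity] = gestures
    return out


def simulate_labeled_gestures(
    config: SimConfig,
    n_per_activity: dict[str, int],
    protocol: str = "natural",
) -> list[Gesture]:
    """Flat collection covering all four activities (training fixtures)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    gestures = []
    for activity in sorted(n_per_activity):
        for k in range(n_per_activity[activity]):
            profile = ParticipantProfile.draw(rng, config.participant_variability)
            gestures.append(
                simulate_gesture(
                    activity,
                    protocol if activity == "medication" else "n/a",
                    profile, rng, config,
                    participant_id=f"G_{activity}_{k:04d}",
                    source_id=f"fix:{activity}:{k}",
                )
            )
    return gestures
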