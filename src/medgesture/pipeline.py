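"""End-to-end orchestration: simulate -> validate -> prepare -> train ->
evaluate, with every stage seeded from one global seed and every output
directory carrying the exact configuration that produced it.

The global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``; stage k always receives child k,
so partial reruns of a later stage reuse the same stream.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import yaml

from . import gestures as ga
from . import lstm, metrics, simulate, windows
from . import errors
from .errors import MedGestureError
from .sensor_io import CLASS_ORDER, read_annotations, read_sensor_csv, standardize_rate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "prepare", "train", "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Parameters of one end-to-end run."""

    out_root: str = "medgesture_run"
    seed: int = 7
    # simulate
    participants: int = 28
    days: int = 5
    gestures_per_day: int = 10
    protocols: tuple = ("natural", "scripted")
    noise_sd: float = 0.05
    secondary_counts: dict | None = None
    # prepare
    window_size: int = 150
    overlap: int = 10
    ratio: float = 0.8
    split_mode: str = "leakage_safe"
    # train
    epochs: int = 150
    batch_size: int = 1024
    learning_rate: float = 0.0025
    l2_lambda: float = 1e-4
    # evaluate
    positive_class: str = "medication"

    def stage_seed(self, stage: str) -> int:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(children[STAGES.index(stage)].generate_state(1)[0] % 2**31)


def _dump_config(config: RunConfig, out: pathlib.Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    block = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(block))


def validate_directory(sensors_dir, annotations_dir=None, rate: float = 25.0):
    """Read every session in a directory, extract and screen its gestures.

    Expects the simulator's naming (``*_sensor.csv`` / ``*_annotations.csv``);
    ``annotations_dir`` defaults to the sensor directory.
    """
    sensors_dir = pathlib.Path(sensors_dir)
    annotations_dir = pathlib.Path(annotations_dir or sensors_dir)
    gestures = []
    sensor_files = sorted(sensors_dir.glob("*_sensor.csv"))
    if not sensor_files:
        raise MedGestureError(f"no *_sensor.csv files found in {sensors_dir}")
    for sensor_path in sensor_files:
        ann_path = annotations_dir / sensor_path.name.replace("_sensor", "_annotations")
        if not ann_path.exists():
            raise MedGestureError(f"missing annotation file {ann_path}")
        log = standardize_rate(read_sensor_csv(sensor_path), rate)
        anns = read_annotations(ann_path)
        gestures.extend(ga.extract_gestures(log, anns))
    screened = ga.flag_outliers(gestures)
    corrected = []
    for g in screened:
        if g.validity == ga.UPPER_OUTLIER:
            for child in simulate_split(g):
                corrected.append(child)
        else:
            corrected.append(g)
    return corrected


def simulate_split(g):
    """Upper-outlier correction: split at quiet runs, then trim children."""
    children = ga.split_multi_event(g)
    if len(children) == 1:
        children = [ga.trim_gesture(g)]
    return children


def run_end_to_end(config: RunConfig) -> metrics.MetricReport:
    """Execute all five stages, persisting artifacts under ``out_root``.

    Returns the per-activity metric report of the best model snapshot.
    """
    root = pathlib.Path(config.out_root)
    _dump_config(config, root)

    # --- simulate
    sim_dir = root / "sessions"
    sim_config = simulate.SimConfig(
        participants=config.participants,
        days=config.days,
        gestures_per_day=config.gestures_per_day,
        protocols=tuple(config.protocols),
        noise_sd=config.noise_sd,
        seed=config.stage_seed("simulate"),
    )
    simulate.simulate_study(sim_config, sim_dir)
    _dump_config(config, sim_dir)
    logger.info("simulated %d sessions", config.participants * config.days)

    # --- validate
    gestures = validate_directory(sim_dir)
    report_dir = root / "validation"
    report_dir.mkdir(parents=True, exist_ok=True)
    ga.validation_report(gestures).to_csv(report_dir / "report.csv", index=False)
    _dump_config(config, report_dir)
    usable = [g for g in gestures if g.validity in (ga.VALID, ga.CORRECTED)]

    # --- secondary activities
    secondary = simulate.simulate_secondary_sets(
        dataclasses.replace(sim_config, seed=config.stage_seed("simulate") + 1),
        counts=config.secondary_counts,
    )
    for lst in secondary.values():
        usable.extend(lst)

    # --- prepare
    ds = windows.build_dataset(
        usable,
        window_size=config.window_size,
        overlap=config.overlap,
        ratio=config.ratio,
        seed=config.stage_seed("prepare"),
        mode=config.split_mode,
    )
    data_dir = root / "dataset"
    windows.save_dataset(ds, data_dir)
    _dump_config(config, data_dir)

    # --- train
    model_config = lstm.ModelConfig(
        window_size=config.window_size,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        l2_lambda=config.l2_lambda,
        seed=config.stage_seed("train"),
    )
    X_train, Y_train = ds.subset("train")
    X_test, Y_test = ds.subset("test")
    best, final, history = lstm.train(X_train, Y_train, X_test, Y_test, model_config)
    model_dir = root / "model"
    lstm.save_model(best, model_dir)
    _dump_config(config, model_dir)

    # --- evaluate
    eval_dir = root / "evaluation"
    eval_dir.mkdir(parents=True, exist_ok=True)
    predicted = best.predict_labels(X_test)
    true = ds.labels[ds.split == "test"]
    matrix = metrics.confusion_multiclass(true, predicted, CLASS_ORDER)
    report = metrics.metric_table(matrix)
    report.to_csv(eval_dir / "metrics.csv")
    try:
        metrics.binary_report(matrix, config.positive_class).to_csv(
            eval_dir / "confusion_binary.csv"
        )
    except errors.UndefinedMetricError as err:
        # an empty predicted-label column leaves the percentages undefined
        (eval_dir / "confusion_binary.csv").write_text(f"N/A,{err}\n")
    np.savetxt(eval_dir / "confusion_counts.csv", matrix, fmt="%d", delimiter=",")
    _dump_config(config, eval_dir)
    return report
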