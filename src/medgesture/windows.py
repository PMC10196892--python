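"""Turning validated gestures into balanced, windowed, one-hot training data.

The classifier consumes fixed-length windows of 150 consecutive samples
(x, y, z per row) with 10 samples of overlap between consecutive windows,
i.e. a stride of 140.  Each window is labeled with the mode of its
per-sample activity labels; ties break to the earliest label in the fixed
class order.  Minority activities are balanced by whole-gesture repetition
before the 80:20 train/test split.

Two split modes exist: ``study_faithful`` shuffles windows after balancing
and cuts 80:20 (repeated copies of one gesture can then land on both sides),
while the default ``leakage_safe`` assigns whole gestures to one side only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import BalancingError, ConfigurationError, SchemaError
from .gestures import Gesture
from .sensor_io import CLASS_ORDER

logger = logging.getLogger(__name__)

WINDOW_SIZE = 150
OVERLAP = 10


@dataclass
class WindowedDataset:
    """Windows, aligned labels and the train/test assignment.

    Attributes
    ----------
    values:
        float64 array (n_windows, window_size, 3).
    labels:
        activity label per window.
    onehot:
        (n_windows, n_classes) one-hot matrix aligned to ``labels``.
    class_order:
        fixed label ordering defining one-hot columns and tie-breaks.
    split:
        'train' or 'test' per window.
    source_ids:
        originating gesture identifier per window.
    """

    values: np.ndarray
    labels: np.ndarray
    onehot: np.ndarray
    class_order: tuple
    split: np.ndarray
    source_ids: np.ndarray

    def subset(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, onehot) for one partition."""
        m = self.split == part
        return self.values[m], self.onehot[m]

    def __len__(self) -> int:
        return len(self.labels)


def balance_classes(gestures: list[Gesture], seed: int) -> list[Gesture]:
    """Repeat whole minority-class gestures until per-activity sample totals
    are within 95% of the largest activity's.

    Originals are always retained; repetition cycles deterministically
    through a seeded shuffle of each minority activity's gestures, so no
    gesture is over-represented before its peers are reused once.
    """
    by_act: dict[str, list[Gesture]] = {}
    for g in gestures:
        by_act.setdefault(g.activity, []).append(g)
    for act, lst in by_act.items():
        if not any(len(g) for g in lst):
            raise BalancingError(f"activity {act!r} has no valid gestures")
    totals = {a: sum(len(g) for g in lst) for a, lst in by_act.items()}
    target = max(totals.values())
    rng = np.random.default_rng(seed)
    out = list(gestures)
    for act in sorted(by_act):
        lst = by_act[act]
        order = rng.permutation(len(lst))
        total, i = totals[act], 0
        while total < 0.95 * target:
            g = lst[order[i % len(lst)]]
            out.append(g)
            total += len(g)
            i += 1
        if i:
            logger.info("balanced %s: +%d repeats (%d -> %d samples)",
                        act, i, totals[act], total)
    return out


def enumerate_offsets(length: int, window_size: int, stride: int) -> list[int]:
    """Start offsets of full windows in a stream of ``length`` samples."""
    return list(range(0, length - window_size + 1, stride))


def mode_label(labels, class_order=CLASS_ORDER) -> str:
    """Most frequent label; ties break to the earliest label in class_order."""
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for lab in class_order:
        if counts.get(lab, 0) == best:
            return lab
    raise SchemaError(f"labels {sorted(counts)} not all in class_order")


def windows_from_stream(
    values: np.ndarray,
    labels,
    window_size: int = WINDOW_SIZE,
    overlap: int = OVERLAP,
    class_order=CLASS_ORDER,
):
    """Slice one contiguous labeled stream into overlapping windows.

    Returns (stacked windows, window labels).  Windows start at offsets
    0, s, 2s, ... with stride s = window_size - overlap; a trailing partial
    window is discarded.  Window label = mode of per-sample labels.
    """
    if not window_size > overlap >= 0:
        raise ConfigurationError("need window_size > overlap >= 0")
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    stride = window_size - overlap
    offsets = enumerate_offsets(len(values), window_size, stride)
    if not offsets:
        return np.empty((0, window_size, 3)), []
    wins = np.stack([values[o : o + window_size] for o in offsets])
    labs = [mode_label(labels[o : o + window_size], class_order) for o in offsets]
    return wins, labs


def make_windows(
    gestures: list[Gesture],
    window_size: int = WINDOW_SIZE,
    overlap: int = OVERLAP,
    class_order=CLASS_ORDER,
):
    """Window every gesture segment independently (no window bridges two
    gestures).  Returns (values, labels, source_ids) arrays.

    Gestures shorter than one window contribute nothing; their count is
    logged rather than raised, since short-but-valid gestures are expected.
    """
    chunks, labs, srcs, skipped = [], [], [], 0
    for g in gestures:
        if len(g) < window_size:
            skipped += 1
            continue
        w, l = windows_from_stream(
            g.xyz, [g.activity] * len(g), window_size, overlap, class_order
        )
        chunks.append(w)
        labs.extend(l)
        srcs.extend([g.source_id] * len(w))
    if skipped:
        logger.info("make_windows: %d gestures shorter than %d samples skipped",
                    skipped, window_size)
    if not chunks:
        return np.empty((0, window_size, 3)), np.array([]), np.array([])
    return np.concatenate(chunks), np.array(labs), np.array(srcs)


def one_hot(labels, class_order=CLASS_ORDER) -> np.ndarray:
    """Encode labels as rows with a single 1 at the class_order index."""
    index = {lab: i for i, lab in enumerate(class_order)}
    try:
        cols = [index[lab] for lab in labels]
    except KeyError as e:
        raise SchemaError(f"label {e.args[0]!r} not in class_order {class_order}")
    out = np.zeros((len(cols), len(class_order)))
    out[np.arange(len(cols)), cols] = 1.0
    return out


def split_train_test(
    values: np.ndarray,
    labels: np.ndarray,
    source_ids: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "leakage_safe",
    class_order=CLASS_ORDER,
) -> WindowedDataset:
    """Assign windows to train/test.

    ``study_faithful``: seeded uniform shuffle of windows, then an 80:20 cut
    — the study's order of operations (balance, then split), which lets
    repeated copies of a gesture straddle the boundary.  ``leakage_safe``
    (default): whole source gestures are assigned to one side, walking a
    seeded shuffle of gestures until the train side holds ~ratio of windows.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError("ratio must be in (0, 1)")
    n = len(labels)
    if n < 5:
        raise ConfigurationError("need at least 5 windows to split")
    rng = np.random.default_rng(seed)
    split = np.full(n, "test", dtype=object)
    if mode == "study_faithful":
        order = rng.permutation(n)
        n_train = int(round(ratio * n))
        split[order[:n_train]] = "train"
    elif mode == "leakage_safe":
        ids = list(dict.fromkeys(source_ids))  # first-appearance order
        order = rng.permutation(len(ids))
        target = ratio * n
        train_ids, got = set(), 0
        for k in order:
            if got >= target:
                break
            train_ids.add(ids[k])
            got += int(np.sum(source_ids == ids[k]))
        split[np.isin(source_ids, list(train_ids))] = "train"
    else:
        raise ConfigurationError(f"unknown split mode {mode!r}")
    return WindowedDataset(
        values=values,
        labels=np.asarray(labels),
        onehot=one_hot(labels, class_order),
        class_order=tuple(class_order),
        split=split,
        source_ids=np.asarray(source_ids),
    )


def build_dataset(
    gestures: list[Gesture],
    window_size: int = WINDOW_SIZE,
    overlap: int = OVERLAP,
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "leakage_safe",
    balance: bool = True,
    class_order=CLASS_ORDER,
) -> WindowedDataset:
    """Balance, window and split in one call (the `prepare` pipeline stage)."""
    if balance:
        gestures = balance_classes(gestures, seed=seed)
    values, labels, srcs = make_windows(gestures, window_size, overlap, class_order)
    return split_train_test(values, labels, srcs, ratio, seed, mode, class_order)


def save_dataset(ds: WindowedDataset, out_dir) -> None:
    """Persist as windows.npy + labels.csv + split.csv (format v1)."""
    import pathlib

    import pandas as pd

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "windows.npy", ds.values)
    pd.DataFrame({"label": ds.labels, "source_id": ds.source_ids}).to_csv(
        out / "labels.csv", index=False
    )
    pd.DataFrame({"split": ds.split}).to_csv(out / "split.csv", index=False)
    (out / "FORMAT").write_text(
        "medgesture dataset v1: windows.npy (n,%d,3), labels.csv, split.csv\n"
        % ds.values.shape[1]
    )


def load_dataset(in_dir, class_order=CLASS_ORDER) -> WindowedDataset:
    import pathlib

    import pandas as pd

    p = pathlib.Path(in_dir)
    values = np.load(p / "windows.npy")
    meta = pd.read_csv(p / "labels.csv")
    split = pd.read_csv(p / "split.csv")["split"].to_numpy(dtype=object)
    labels = meta["label"].to_numpy()
    return WindowedDataset(
        values=values,
        labels=labels,
        onehot=one_hot(labels, class_order),
        class_order=tuple(class_order),
        split=split,
        source_ids=meta["source_id"].to_numpy(),
    )
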