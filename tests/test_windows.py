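import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gesture
from medgesture.errors import BalancingError, ConfigurationError, SchemaError
from medgesture.sensor_io import CLASS_ORDER
from medgesture.windows import (
    balance_classes,
    build_dataset,
    enumerate_offsets,
    load_dataset,
    make_windows,
    mode_label,
    one_hot,
    save_dataset,
    split_train_test,
    windows_from_stream,
)


def brute_force_offsets(length, window_size, stride):
    out, start = [], 0
    while start + window_size <= length:
        out.append(start)
        start += stride
    return out


def brute_force_mode(labels, class_order):
    best_count, best = -1, None
    for lab in class_order:
        c = sum(1 for x in labels if x == lab)
        if c > best_count:
            best_count, best = c, lab
    return best


class TestWindowing:
    def test_310_samples_gives_two_windows(self):
        values = np.zeros((310, 3))
        wins, labs = windows_from_stream(values, ["eating"] * 310)
        assert wins.shape == (2, 150, 3)
        assert enumerate_offsets(310, 150, 140) == [0, 140]

    def test_exact_window_boundary(self):
        wins, labs = windows_from_stream(np.zeros((150, 3)), ["jogging"] * 150)
        assert wins.shape == (1, 150, 3)
        assert labs == ["jogging"]

    def test_count_formula_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for length in rng.integers(1, 1000, 200):
            expected = brute_force_offsets(length, 150, 140)
            assert enumerate_offsets(int(length), 150, 140) == expected
            if length >= 150:
                assert len(expected) == (length - 150) // 140 + 1

    def test_mode_label_dominant_activity(self):
        labels = ["medication"] * 90 + ["eating"] * 60
        wins, labs = windows_from_stream(np.zeros((150, 3)), labels)
        assert labs == ["medication"]

    def test_mode_tie_breaks_to_class_order(self):
        labels = ["smoking"] * 75 + ["eating"] * 75
        assert mode_label(labels) == "eating"  # eating precedes smoking

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(CLASS_ORDER), min_size=1, max_size=40))
    def test_mode_equals_brute_force(self, labels):
        assert mode_label(labels) == brute_force_mode(labels, CLASS_ORDER)

    def test_short_gesture_contributes_nothing(self):
        g = make_gesture(2.0)  # 51 samples < 150
        values, labels, srcs = make_windows([g])
        assert len(labels) == 0

    def test_invalid_overlap(self):
        with pytest.raises(ConfigurationError):
            windows_from_stream(np.zeros((200, 3)), ["eating"] * 200,
                                window_size=10, overlap=10)


class TestOneHot:
    def test_examples(self):
        m = one_hot(["medication", "jogging"])
        np.testing.assert_array_equal(m, [[1, 0, 0, 0], [0, 0, 0, 1]])

    def test_row_sums(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(CLASS_ORDER, 50)
        m = one_hot(labels)
        np.testing.assert_array_equal(m.sum(axis=1), np.ones(50))
        assert np.all((m == 0) | (m == 1))

    def test_unknown_label(self):
        with pytest.raises(SchemaError):
            one_hot(["sleeping"])


class TestBalance:
    def test_exact_doubling(self):
        a = [make_gesture(3.96, activity="medication", source=f"a{k}") for k in range(10)]
        b = [make_gesture(3.96, activity="eating", source=f"b{k}") for k in range(5)]
        out = balance_classes(a + b, seed=0)
        assert sum(g.activity == "eating" for g in out) == 10
        assert sum(g.activity == "medication" for g in out) == 10

    def test_already_balanced_unchanged(self):
        gs = [make_gesture(4, activity=a, source=f"{a}{k}")
              for a in ("medication", "eating") for k in range(3)]
        assert balance_classes(gs, seed=0) == gs

    def test_minority_reaches_95_percent(self):
        a = [make_gesture(4, activity="medication", source=f"a{k}") for k in range(7)]
        b = [make_gesture(4, activity="eating", source=f"b{k}") for k in range(3)]
        out = balance_classes(a + b, seed=1)
        tot = lambda act: sum(len(g) for g in out if g.activity == act)
        assert tot("eating") >= 0.95 * tot("medication")
        # balancing never removes data
        assert all(g in out for g in a + b)

    def test_missing_activity_errors(self):
        empty = make_gesture(4, activity="smoking")
        empty.time_ms = empty.time_ms[:0]
        empty.xyz = empty.xyz[:0]
        with pytest.raises(BalancingError, match="smoking"):
            balance_classes([make_gesture(4), empty], seed=0)


class TestSplit:
    def _windows(self, n=100, n_gestures=10):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((n, 150, 3))
        labels = rng.choice(CLASS_ORDER, n)
        srcs = np.repeat([f"g{k}" for k in range(n_gestures)], n // n_gestures)
        return values, labels, srcs

    def test_cardinality_80_20(self):
        ds = split_train_test(*self._windows(), ratio=0.8, seed=0, mode="study_faithful")
        assert int((ds.split == "train").sum()) == 80
        assert int((ds.split == "test").sum()) == 20

    def test_same_seed_identical(self):
        args = self._windows()
        a = split_train_test(*args, seed=5)
        b = split_train_test(*args, seed=5)
        np.testing.assert_array_equal(a.split, b.split)

    def test_leakage_safe_never_straddles(self):
        values, labels, srcs = self._windows(n=50, n_gestures=10)  # 5 windows/gesture
        ds = split_train_test(values, labels, srcs, seed=2, mode="leakage_safe")
        train_ids = set(ds.source_ids[ds.split == "train"])
        test_ids = set(ds.source_ids[ds.split == "test"])
        assert not (train_ids & test_ids)

    def test_bad_ratio(self):
        with pytest.raises(ConfigurationError):
            split_train_test(*self._windows(), ratio=1.5)


class TestRoundTrip:
    def test_save_load_dataset(self, tmp_path):
        gs = [make_gesture(8, activity=a, source=f"{a}{k}")
              for a in CLASS_ORDER for k in range(3)]
        ds = build_dataset(gs, seed=0)
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        np.testing.assert_array_equal(back.values, ds.values)
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_array_equal(back.split, ds.split)
        np.testing.assert_array_equal(back.onehot, ds.onehot)
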