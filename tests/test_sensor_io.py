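import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from medgesture.errors import ConfigurationError, MalformedInputError, SchemaError
from medgesture.sensor_io import (
    AnnotationRecord,
    SensorLog,
    read_annotations,
    read_sensor_csv,
    standardize_rate,
    write_annotations,
    write_sensor_csv,
)


def make_log(time_ms, xyz=None, rate=25.0):
    time_ms = np.asarray(time_ms, dtype=np.int64)
    if xyz is None:
        xyz = np.arange(3 * len(time_ms), dtype=float).reshape(-1, 3)
    return SensorLog("P01", time_ms, xyz, nominal_rate=rate)


class TestReadWriteSensorCsv:
    def test_three_row_identity(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "timestamp,x,y,z\n"
            "2023-05-01T10:00:00.000,0.1,0.2,0.3\n"
            "2023-05-01T10:00:00.040,0.4,0.5,0.6\n"
            "2023-05-01T10:00:00.080,0.7,0.8,0.9\n"
        )
        log = read_sensor_csv(path)
        assert len(log) == 3
        np.testing.assert_array_equal(np.diff(log.time_ms), [40, 40])
        np.testing.assert_allclose(log.xyz[1], [0.4, 0.5, 0.6])

    def test_out_of_order_rows_sorted(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "timestamp,x,y,z\n"
            "2023-05-01T10:00:00.080,3,3,3\n"
            "2023-05-01T10:00:00.000,1,1,1\n"
            "2023-05-01T10:00:00.040,2,2,2\n"
        )
        log = read_sensor_csv(path)
        np.testing.assert_array_equal(log.xyz[:, 0], [1, 2, 3])

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "timestamp,x,y,z\n"
            "2023-05-01T10:00:00.000,1,1,1\n"
            "2023-05-01T10:00:00.000,9,9,9\n"
            "2023-05-01T10:00:00.040,2,2,2\n"
        )
        log = read_sensor_csv(path)
        assert len(log) == 2
        assert log.xyz[0, 0] == 1

    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        log = make_log(np.arange(100) * 40, rng.standard_normal((100, 3)))
        write_sensor_csv(log, tmp_path / "rt.csv")
        back = read_sensor_csv(tmp_path / "rt.csv")
        np.testing.assert_array_equal(back.time_ms, log.time_ms)
        np.testing.assert_array_equal(back.xyz, log.xyz)  # exact, not approx

    def test_write_empty_log_errors_and_creates_no_file(self, tmp_path):
        log = make_log([0], np.zeros((1, 3)))
        log.time_ms = log.time_ms[:0]
        log.xyz = log.xyz[:0]
        target = tmp_path / "empty.csv"
        with pytest.raises(ConfigurationError):
            write_sensor_csv(log, target)
        assert not target.exists()

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timestamp,x,y\n2023-05-01T10:00:00.000,1,2\n")
        with pytest.raises(SchemaError, match="z"):
            read_sensor_csv(path)

    def test_unparseable_timestamp_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "timestamp,x,y,z\n"
            "2023-05-01T10:00:00.000,1,2,3\n"
            "not-a-time,4,5,6\n"
        )
        with pytest.raises(MalformedInputError, match="line 3"):
            read_sensor_csv(path)


class TestAnnotations:
    def test_two_valid_intervals(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(
            "participant_id,activity,protocol,start,end\n"
            "P01,medication,natural,2023-05-01T10:00:05.000,2023-05-01T10:00:25.000\n"
            "P01,eating,n/a,2023-05-01T10:00:00.000,2023-05-01T10:00:03.000\n"
        )
        records = read_annotations(path)
        assert len(records) == 2
        assert records[0].activity == "eating"  # sorted by start
        assert records[1].duration_s == 20.0

    def test_degenerate_interval_rejected(self, tmp_path, caplog):
        path = tmp_path / "a.csv"
        path.write_text(
            "participant_id,activity,protocol,start,end\n"
            "P01,medication,natural,2023-05-01T10:00:05.000,2023-05-01T10:00:05.000\n"
            "P01,medication,natural,2023-05-01T10:00:06.000,2023-05-01T10:00:09.000\n"
        )
        with caplog.at_level("WARNING"):
            records = read_annotations(path)
        assert len(records) == 1
        assert "rejected 1" in caplog.text

    def test_unknown_activity_lists_allowed(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(
            "participant_id,activity,protocol,start,end\n"
            "P01,sleeping,natural,2023-05-01T10:00:05.000,2023-05-01T10:00:06.000\n"
        )
        with pytest.raises(SchemaError, match="medication"):
            read_annotations(path)

    def test_write_read_round_trip(self, tmp_path):
        records = [
            AnnotationRecord("P01", "medication", "natural", 1_000, 19_000),
            AnnotationRecord("P01", "jogging", "n/a", 30_000, 90_000),
        ]
        write_annotations(records, tmp_path / "a.csv")
        assert read_annotations(tmp_path / "a.csv") == records


class TestStandardizeRate:
    def test_decimation_50_to_25(self):
        log = make_log(np.arange(100) * 20, rate=50.0)  # 50 Hz, 100 samples
        out = standardize_rate(log, 25.0)
        assert len(out) == 50
        np.testing.assert_array_equal(np.diff(out.time_ms), 40)
        # decimation keeps raw values (every other sample)
        np.testing.assert_array_equal(out.xyz, log.xyz[::2][:50])

    def test_25hz_identity(self, rate25_log):
        out = standardize_rate(rate25_log, 25.0)
        np.testing.assert_array_equal(out.time_ms, rate25_log.time_ms)
        np.testing.assert_array_equal(out.xyz, rate25_log.xyz)

    def test_upsampling_ramp_hits_linear_interpolants(self):
        # 12.5 Hz ramp x(t) = t: the 25 Hz midpoints must be exact averages
        time_ms = np.arange(50) * 80
        t = time_ms / 1000.0
        log = make_log(time_ms, np.column_stack([t, t, t]), rate=12.5)
        out = standardize_rate(log, 25.0)
        expected = out.time_ms / 1000.0
        np.testing.assert_allclose(out.xyz[:, 0], expected, atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        log = make_log(np.cumsum(rng.integers(10, 60, 200)),
                       rng.standard_normal((200, 3)))
        once = standardize_rate(log, 25.0)
        twice = standardize_rate(once, 25.0)
        np.testing.assert_array_equal(once.time_ms, twice.time_ms)
        np.testing.assert_array_equal(once.xyz, twice.xyz)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 300),
        dt_ms=st.integers(5, 200),
        target=st.sampled_from([10.0, 25.0, 40.0]),
    )
    def test_duration_conserved(self, n, dt_ms, target):
        assume((n - 1) * dt_ms >= 1000.0 / target)
        log = make_log(np.arange(n) * dt_ms,
                       np.zeros((n, 3)), rate=1000.0 / dt_ms)
        out = standardize_rate(log, target)
        assert abs(out.duration_s - log.duration_s) <= 1.0 / target + 1e-9
        assert np.all(np.diff(out.time_ms) > 0)

    def test_too_short_log_errors(self):
        log = make_log([0, 10], np.zeros((2, 3)))
        with pytest.raises(ConfigurationError):
            standardize_rate(log, 25.0)
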