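import numpy as np
import pytest

from medgesture.gestures import Gesture
from medgesture.sensor_io import SensorLog


@pytest.fixture
def rate25_log():
    """60 s of 25 Hz data, x(t) = t in seconds, y = 2t, z = 0."""
    n = 60 * 25 + 1
    time_ms = np.arange(n, dtype=np.int64) * 40
    t = time_ms / 1000.0
    xyz = np.column_stack([t, 2 * t, np.zeros(n)])
    return SensorLog("P01", time_ms, xyz, nominal_rate=25.0)


def make_gesture(duration_s, activity="medication", protocol="natural",
                 rate=25.0, xyz=None, source="g0"):
    n = int(round(duration_s * rate)) + 1
    time_ms = np.round(np.arange(n) * 1000.0 / rate).astype(np.int64)
    if xyz is None:
        rng = np.random.default_rng(abs(hash((duration_s, activity))) % 2**31)
        xyz = rng.standard_normal((n, 3))
    return Gesture("P01", activity, protocol, time_ms, xyz[:n], source_id=source)


def burst_and_quiet(burst_s=18.0, quiet_s=10.0, rate=25.0, n_bursts=2, amp=2.0):
    """Alternating active/quiet segments; returns (xyz, quiet boundaries)."""
    rng = np.random.default_rng(42)
    chunks = []
    for k in range(n_bursts):
        nb = int(burst_s * rate)
        burst = amp * np.sin(np.linspace(0, 20 * np.pi, nb))[:, None] * np.ones(3)
        burst += 0.2 * rng.standard_normal((nb, 3))
        chunks.append(burst)
        if k < n_bursts - 1:
            nq = int(quiet_s * rate)
            chunks.append(0.001 * rng.standard_normal((nq, 3)))
    return np.concatenate(chunks)
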