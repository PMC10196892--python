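"""Extract self-reported events from a session and screen their durations.

Writes a small simulated session to a temporary directory, reads it back
through the standard CSV loaders, cuts out the annotated segments, and
applies the outlier rules: events <= 8 s are implausibly short (start/stop
tapped in quick succession), events >= 100 s usually contain several events
or unrelated activity.
"""

import tempfile

from medgesture.gestures import duration_stats, extract_gestures, flag_outliers
from medgesture.pipeline import validate_directory
from medgesture.simulate import SimConfig, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    simulate_study(
        SimConfig(participants=2, days=2, gestures_per_day=10,
                  protocols=("natural",), idle_mean_s=10.0,
                  frac_too_short=0.10, seed=21),
        tmp,
    )
    gestures = validate_directory(tmp)

stats = duration_stats(gestures)
print(f"extracted {stats.n} gestures: mean {stats.mean:.1f} s, "
      f"median {stats.median:.1f} s, range {stats.min:.1f}-{stats.max:.1f} s")
for validity in ("valid", "lower_outlier", "upper_outlier", "corrected", "invalid"):
    n = sum(g.validity == validity for g in gestures)
    if n:
        print(f"  {validity:>14}: {n}")

# The 10% deliberately corrupted annotations show up as lower outliers;
# those are discarded before training, matching the finding that sampled
# short self-reports were all invalid.
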