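# Methods

## Problem and data model

The pipeline classifies fixed-length windows of wrist-worn tri-axial
accelerometer data into four activities — medication taking, eating,
smoking, jogging — with medication taking as the class of interest for
adherence monitoring. A recording session is a CSV of timestamped x/y/z
samples, nominally 25 Hz; self-reported events arrive as (participant,
activity, protocol, start, end) intervals in a companion CSV. Timestamps
are held internally as integer epoch milliseconds. Acceleration units are
treated as opaque (device units; whether gravity is included is not
specified by the logging hardware) but must be consistent across datasets.

Logs from other rates are standardised to 25 Hz: oversampled input is
decimated onto the target grid taking the nearest *preceding* raw sample
(no values are fabricated when discarding data), undersampled input is
linearly interpolated per axis — linear being the minimal assumption when
nothing more is known about the sensor. The output grid preserves total
duration to within one sample period, and standardisation is idempotent.

## Event validation

Event segments are extracted on the closed interval start ≤ t ≤ end (the
most inclusive deterministic convention; one sample more or fewer is
immaterial at 25 Hz but the choice is pinned). Durations are screened
against fixed bounds: ≤ 8 s → lower outlier, ≥ 100 s → upper outlier.
Lower outliers are discarded from training by default — short self-reports
are overwhelmingly start/stop taps in quick succession, not real events.
Upper outliers are corrected automatically, operationalising what a human
auditor does:

* **split_multi_event** cuts a recording at sustained quiet runs (several
  consecutively-taken medications reported as one event);
* **trim_gesture** removes quiet padding from the ends (unrelated recording
  around one event).

"Quiet" is defined per sample as the acceleration magnitude deviating from
its local (~1 s rolling) median by less than a threshold, default 5% of the
segment's magnitude interquartile range. A resting wrist reads a steady
gravity magnitude, so low local deviation is stillness; a whole-segment
median would mislabel idle stretches in mostly-active segments, which is why
the local form is used. Splitting requires a quiet run of at least 5 s
(configurable); children concatenate exactly back to the parent. Trimming
iterates to a fixed point so it is idempotent. Duration statistics use the
sample standard deviation (n−1); whether the original study used n or n−1
is unstated, so the choice is documented rather than inferred.

## Dataset construction

Windows are 150 samples × 3 axes, consecutive windows sharing 10 samples
(stride 140). The stride convention is taken literally from "10 points of
overlap"; many HAR codebases instead use stride 10, so the stride is
exposed as a parameter. (At 25 Hz, 150 samples is 6 s of data, although the
source description calls it ~1.5 s; the implementation follows the stated
150 samples and notes the arithmetic inconsistency without resolving it.)
A window's label is the mode of its per-sample labels, ties broken by the
fixed class order (medication, eating, smoking, jogging). Windows never
bridge two gestures, since inputs arrive gesture-segmented.

Class balance is restored by whole-gesture repetition (cycling through a
seeded shuffle of the minority class) until every activity's sample total
reaches 95% of the largest; originals are never removed. The 80:20
train/test split has two modes: `study_faithful` shuffles windows after
balancing and cuts — the original order of operations, which can place
copies of one gesture on both sides — and the default `leakage_safe`, which
assigns whole gestures to one side. Both are provided deliberately:
fidelity and correctness are different goals, and the mode is recorded with
every dataset.

## Classifier

Architecture: input (150 × 3) → LSTM(64) → LSTM(64) → dense(64, ReLU) →
dense(4) → softmax, with the final LSTM hidden state feeding the dense
head. The LSTM cell is standard (input/forget/cell/output gates); state is
reset per window — windows are independent sequences, the reproducible
reading of "past context is kept in the cell". Forward pass,
backpropagation through time and the optimisers are implemented directly in
NumPy; a numerical central-difference gradient check in the test suite is
the independent oracle for the backward pass.

Training hyperparameters at full scale: learning rate 0.0025, batch 1024,
150 epochs, L2 penalty on all weight matrices. Choices the source
architecture leaves open, fixed here and exposed in `ModelConfig`:

| parameter | default | rationale |
| --- | --- | --- |
| loss | categorical cross-entropy | standard for one-hot multi-class |
| optimizer | Adam (SGD available) | default for LSTM training; lr as stated |
| l2_lambda | 1e-4 | L2 is used but no coefficient is given |
| dense activation | ReLU | conventional rectifying nonlinearity |
| weight init | Glorot uniform, forget-gate bias 1 | survives long unrolls |
| clip_norm | 5.0 (global L2 norm) | see below |

Gradient clipping is a numerical-stability measure: over a 150-step unroll
the gradient norm occasionally spikes and a single unclipped Adam step can
throw training into divergence; clipping rescales the step without changing
its direction. Training records accuracy and mean cross-entropy on both
partitions every epoch and returns both the best-by-test-accuracy snapshot
and the final one. With a fixed seed and single-threaded BLAS, runs are
bit-reproducible.

Scaled-down runs (tests, examples) use batch 64 or 32 rather than 1024:
with a few hundred training windows, a 1024 batch would mean one gradient
step per epoch, so smaller batches keep the number of updates per epoch
meaningful at desk scale. Epoch counts for those runs (2–20) are likewise
desk-scale choices, stated with each run.

## Evaluation

All metrics derive from the multiclass confusion matrix via one-vs-rest
reduction; formulas are in the README. Zero-denominator metrics are
reported as N/A (NaN), never as 0 — an undefined ratio carries different
information than a zero score. Percentage tables round half away from zero
at one decimal; macro averages are unweighted means of the *rounded*
per-activity entries, rounded again, matching how summary rows of published
metric tables are conventionally assembled. One such published summary row
cannot be reproduced exactly from its own table: the recall average of
(92, 92, 76.9, 100) is 90.225 → 90.2 at one decimal, yet 90.3 is printed;
similarly a printed medication F-measure of 94.3 disagrees with the formula
applied to its printed precision/recall (96.1, 92 → 94.0). The
implementation reproduces the formulas and flags these discrepancies rather
than force-matching the printed digits. The binary
medication/non-medication table reports counts with column-normalised
percentages (% of each *predicted*-label column).

## Synthetic-data generator

The generator emulates the structure of the wear study: 28 participants,
10 events/day × 5 days per protocol (natural + scripted = 2800 events),
25 Hz, one sensor log and one annotation file per participant-day, idle
gaps between events (exponential, mean 60 s, invented and configurable).

Event durations are lognormal per protocol, moment-matched to mean 18.47 s
/ SD 14.34 s (natural) and 20.11 s / SD 20.65 s (scripted). Lognormal is
the natural family here: durations are positive and strongly right-skewed
(minutes-long outliers against a ~17 s median). A two-parameter lognormal
cannot match mean, SD and median simultaneously; mean/SD take priority, so
the model's median (~14.6 s) sits below the study's 17 s.

Each activity is a grammar over mini-activities rendered as piecewise
smooth primitives (ramps, raised-cosine bumps, windowed oscillations):
medication = open-bottle, dispense, hand-to-mouth, pill-into-mouth,
hand-off-mouth, pick-up-water, drink-water (with the hallmark gradual
y-axis rise), lower-cup, close-bottle — fixed order when scripted, random
interleaving of the bottle/pill/water sub-chains preserving intra-chain
order when natural; eating and smoking are repeated bite/puff motifs;
jogging is quasi-periodic at a 2.5 Hz stride frequency. Each activity also
carries a static wrist-orientation (gravity) offset — holding a bottle, a
cigarette, food, or swinging the arm each put the watch in a characteristic
attitude — which is a large part of what makes the classes separable at low
noise. Per-participant scale/offset jitter and additive Gaussian noise
(default SD 0.05 in template units of order 1) are applied on top.
Amplitudes are arbitrary units; the templates target qualitative
morphology, not numerical fidelity to any real recording.

A configurable fraction of *annotations* is deliberately corrupted to
exercise validation: 3% mark a < 8 s sub-interval of a normal event, 0.5%
merge an event's record into its predecessor (several medications reported
as one) — proportions echoing the study's observed outlier rates without
claiming to reproduce them. Corruption never alters the underlying
waveforms or the gesture count, so the generated study always contains
exactly participants × days × per-day × protocols events.

**What passing on this data does and does not show.** The synthetic classes
are far more separable than real wrist data: real gestures vary in
execution, orientation and context far beyond per-participant jitter plus
Gaussian noise, and real medication/smoking events share hand-to-mouth
morphology that templates only partially capture. High accuracy here
validates the pipeline mechanics — extraction, windowing, balancing,
optimisation, evaluation — not field performance. The secondary
eating/smoking/jogging collections default to a ~1:100 scale-down of their
real counterparts' gesture counts and are labelled synthetic stand-ins.

## Reproducibility

Every stochastic component takes a seed; the end-to-end pipeline fans one
global seed out to per-stage seeds via `numpy.random.SeedSequence.spawn`
(stage k gets child k, so a later stage reruns identically even if earlier
stages are skipped). Each stage's output directory carries the exact run
configuration as YAML. Two runs with the same configuration and seed
produce byte-identical artifacts on a single thread.

## Known limitations

* The automated split/trim corrections approximate a human auditor's
  judgement with one scalar stillness statistic; pathological segments
  (e.g. slow drift during idle) can defeat them.
* Natural-sequence generation permutes sub-chains but does not model
  interruptions by unrelated activities, which real natural events contain.
* Per-activity one-vs-rest "accuracy" is implemented as stated; whether the
  reference table's per-activity accuracy used the same reduction is
  unconfirmed.
* Watch-orientation variants (left wrist, inverted wear) are not modelled.
* The NumPy LSTM is single-threaded and CPU-bound; it is sized for
  desk-scale experiments, not for training on weeks of raw recordings.
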