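# Methods

## Signal model

The simulator treats interference-pattern surface EMG as colored noise
amplitude-modulated by muscle drive. For channel *c* at time *t*:

    x_c(t) = a(t) · g_c(m) · A · w_c(t) + b_c(t) + ε_c(t)

where `a(t) ∈ [0,1]` is the guide activation, `g_c(m)` the movement's
spatial gain at that electrode, `A` the voluntary amplitude scale,
`w_c(t)` a unit-variance Gaussian carrier band-limited to 10–500 Hz
(4th-order zero-phase Butterworth, matching the amplifier band),
`b_c(t)` involuntary burst activity and `ε_c(t)` white measurement
noise. Samples are rounded and clipped to int16. This is deliberately
not a motor-unit pool or volume-conductor model: it reproduces the
*second-order* structure an RMS-based pipeline sees (spatially patterned
amplitude modulation), which is the property the decoder depends on.
Features of real data it does not emulate: motor-unit discharge
structure, fatigue drift, electrode-skin impedance changes, crosstalk
asymmetries, movement artifacts. Passing tests therefore demonstrate
correctness of the pipeline and the statistical machinery, not clinical
performance.

Key parameters (units; default; rationale):

- `voluntary_scale` (ADC counts; 3000): peak voluntary RMS, leaving
  ~10× headroom in int16 as a gain-4 amplifier would.
- `noise_sd` (counts; 30): baseline noise floor ~1% of full voluntary
  amplitude, typical of a decent dry-electrode contact.
- `activation_maps` (16×2 gains; circular-Gaussian bumps, σ = 1.5 rows,
  distinct centres per movement, mild column asymmetry): compact muscle
  territories around the cuff; pairwise-distinct by construction.
- `hold_time_s` / `cycle_period_s` (s; 1.5 / 7.5): holds at both
  extrema with raised-cosine ramps of (cycle − 2·hold)/2; the activation
  spends exactly half of each cycle at or above 50%, which is what makes
  the labeling arithmetic (45 s rest / 15 s active over three 30-s
  recordings) exact.
- `dead_channels`: channels with no skin contact emit measurement noise
  only.

### Involuntary activity and the SCI-like preset

Non-task-modulated motor-unit activity is modeled as Poisson-timed
bursts with a Hann temporal envelope and a *contiguous* spatial
territory (circular-Gaussian bump at a random row): a spontaneously
firing unit projects to a compact patch of the grid exactly as voluntary
activity does, which is what makes it confusable with intent.
`sci_like_cuff` represents severe spasticity with paresis: voluntary
scale halved (1500 counts) and two burst onsets per second lasting
0.5–2 s each, overlapping into near-continuous involuntary activity
during rest. This regime was chosen deliberately: uncertainty-aware
decoding only has observable work to do when the decoder's error rate
on rest exceeds the miscoverage budget α — with sparse, mild bursts the
calibrated quantile stays below the singleton threshold and conformal
output degenerates to the naive argmax. The default `CuffModel` has no
bursts (a clean able-bodied-like recording).

## Feature pipeline

Windows (32 × 18 int16) enter a sliding queue of 20; a full queue spans
360 samples (~180 ms) and emits one block per push, giving the full
111 Hz frame rate. Each block is reshaped to the physical grid
(channel *i* → row *i* mod 16, column *i* div 16, so channels 0 and 16
are row-adjacent across columns — documented and configurable via
`GridLayout`). Per time sample the grid is padded to 18 × 4 — rows
circularly (the cuff loops), one zero column per side (so the 3 × 3
kernel is applicable at both physical columns; the alternative of both
virtual columns on one side has no physical reading) — and correlated
with the fixed kernel ¼·[[0,1,0],[1,½,1],[0,1,0]]; the kernel is
symmetric, so correlation and convolution coincide. Filtering is purely
spatial and linear, so the batch path (filter the concatenated stream
once, read block RMS off cumulative sums of squares) is exactly
equivalent to the streaming path; a test asserts this. Data are cast to
float before squaring to avoid int16 overflow. RMS per channel gives 32
features; the label is the arithmetic mean of the 9D guide states whose
timestamps fall in the block's span (a span with no guide sample carries
the last known state and is flagged).

An optional software bandpass (4th-order zero-phase Butterworth,
10–500 Hz) exists behind a flag for replaying data not already
band-limited at source; it is off by default because the simulated
amplifier, like the real one, filters at base.

## Labeling, splitting, normalization

A movement's scalar activation is the maximum of the guide state over
the movement's driven (nonzero-target) components — multi-digit
movements need a single scalar and the max preserves the
50%-of-full-flexion semantics. The boundary is inclusive: exactly 50%
is movement. The split is chronological per recording (first 80% train),
never shuffled: streamed features are strongly autocorrelated and a
random split would leak. Whether the original 80/20 is per-recording or
global over the concatenated stream is not determinable; per-recording
is implemented so every movement contributes proportionally to both
partitions. Normalization is z-scoring with training-head statistics
only, SD floored at 1e−8 (a dead electrode yields a near-constant
feature; the floor keeps outputs finite and a warning is emitted).

## Classifier

Default backend: LightGBM gradient-boosted trees, 1000 boosting
iterations, deterministic single-threaded mode, seeded. The backend is
an interface (`estimator=` accepts anything with fit/predict_proba;
`backend="logistic"` is a fast linear alternative used widely in the
test suite where the classifier itself is not under test). Training
requires ≥ 2 classes; probability rows sum to 1.

## Conformal prediction (RAPS)

Scores sort classes by descending probability (stable sort, so ties
break by class order — deterministic); the score of the class at rank
*j* is the cumulative mass through it plus λ·max(0, j − k_reg).
Calibration uses held-out data disjoint from training — here the 20%
tail of each recording is halved into calibration and holdout, since
the protocol has no third session — and q̂ is the ⌈(n+1)(1−α)⌉-th
smallest score (clipped to the maximum; as α → 0 the set grows toward
all classes). Membership is the non-strict rule score ≤ q̂, the
condition under which split-conformal marginal coverage ≥ 1 − α holds
for exchangeable data; the top-1 class is always included, so sets are
never empty. Defaults α = 0.1, λ = 0.01, k_reg = 1 follow the
originating RAPS literature's recommendations. Randomized tie-breaking
is off: a real-time control signal must be reproducible.

The temporal solver passes singleton ("certain") sets through
unchanged, so a sustained switch to a new certain class appears with no
added lag. An uncertain set is resolved by tallying class occurrences
over the last 75 sets (current included; ~0.7 s of history); the most
frequent class wins, a tie keeps the previous output (state holding
beats switching), and a cold-start tie with no previous output falls
back to the set's top-probability member. History inclusion and the
cold-start rule are this package's choices where the procedure is
otherwise underdetermined.

Known limitation, reproduced faithfully: when calibration error is far
above α, q̂ exceeds the singleton threshold for most frames, sets
inflate, and the solver can freeze the output — accuracy then drops
below naive even as stability improves. This mirrors the known clinical
trade-off (steadier control, slower reactions, occasionally worse
frame-wise accuracy).

## Evaluation

Validation replays drive the guide at six repetitions per 45-s span per
movement (cycle 7.5 s) and score every frame, rest between repetitions
included. Per-movement accuracy is correct frames / frames of that
movement; the overall figure is mean ± SD *across movements*. Output
transitions (state switches per replay) measure control stability;
the set-size histogram summarizes decoder certainty.

## Problem sizes and numerical choices

Default experiments use three movements × 30 s training recordings
(~9,900 feature frames) and 3 × 45 s validation replays (~14,900
frames); the conformal coverage property is checked on synthetic
4-class Gaussian data with 2,000-example calibration and holdout sets
over three seeds. Tolerances: sine-RMS closed form within 1%; coverage
within two binomial SDs of 1 − α; labeling durations within 2 frames at
60 Hz (threshold crossings may fall exactly on grid samples). All
randomness flows through explicit integer seeds; identical configs and
seeds give bit-identical streams, features and predictions.
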