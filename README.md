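# myodecode

Headless decoding of motor intent from high-density surface EMG, for
researchers prototyping real-time myocontrol (virtual hands, prostheses,
cursors) without hardware in the loop.

A 32-channel dry-electrode cuff loops around the forearm as a 16-row ×
2-column grid, sampled at 2000 Hz and streamed as non-overlapping
32 × 18 int16 windows (≈111 windows/s). A guide hand, represented as a
9D vector in [0,1]⁹ (thumb flexion/abduction, four finger flexions,
wrist flexion/adduction/pronation), moves sinusoidally at 60 Hz and
provides the labels. The package implements the full decoding chain:

1. **Simulation** — gesture-dependent spatial activation over the grid,
   amplitude-modulated band-limited (10–500 Hz) noise carriers, 16-bit
   quantization, dead channels, and optional involuntary motor-unit
   bursts that corrupt the rest state (`sci_like_cuff`).
2. **Features** — a sliding 20-window queue (360 samples ≈ 180 ms);
   per time sample the grid is circularly padded over rows (the cuff
   loops), zero-padded over columns, and smoothed with the fixed 3×3
   kernel ¼·[[0,1,0],[1,½,1],[0,1,0]]; each block reduces to one RMS
   value per channel — 32 features per frame, ~111 frames/s.
3. **Labeling** — a frame is the movement's class when the guide
   activation (max over the movement's driven components) is ≥ 50% of
   full flexion, rest otherwise; splits are chronological (first 80%
   train), and z-scoring statistics come from the training head only.
4. **Decoding** — a gradient-boosted-tree classifier (LightGBM, 1000
   iterations; any probabilistic estimator pluggable) wrapped in
   regularized adaptive prediction sets (RAPS). With classes sorted by
   descending probability, the nonconformity score at rank *j* is
   Σᵢ≤ⱼ p₍ᵢ₎ + λ·max(0, j − k_reg); calibration takes q̂ as the
   ⌈(n+1)(1−α)⌉/n score quantile, and a prediction set contains every
   class scoring ≤ q̂ (never empty). A singleton set is *certain*;
   uncertain sets are resolved by majority vote over the last 75 sets,
   ties keeping the previous output.
5. **Outputs** — decoded classes drive a 9D hand state with linear
   interpolation (0.25 s transitions at 32 Hz) or a 2D cursor
   (inversion/eversion ↔ left/right, dorsi-/plantarflexion ↔ up/down,
   rest holds); messages are 9 (or 2) little-endian float32 plus a
   uint32 counter.

## Worked example

`examples/03_train_and_validate.py` simulates 30 s of training data per
movement, trains and calibrates the decoder, and scores a fresh
validation replay (six repetitions within 45 s per movement):

```
train/test frames: 7953/1989 (chronological 80/20 per recording)
holdout accuracy:  0.995
conformal qhat:    1.0000 (alpha=0.1)

class            conformal       naive
rest                99.7% (99.7%)
thumb               99.4% (99.4%)
index               99.8% (99.9%)
grasp               99.4% (99.4%)
overall         99.6% +- 0.2% (99.6% +- 0.2%)
transitions   conformal 42, naive 42
```

Per-class rows show conformal accuracy with the naive argmax in
parentheses; "overall" aggregates across movements (mean ± SD), not
across frames. On clean, well-separated synthetic data the two schemes
coincide — almost every prediction set is a singleton. The value of the
conformal wrapper shows in `examples/04_conformal_stability.py`, which
reruns the experiment with weakened voluntary EMG and near-continuous
involuntary bursts: there the conformal output switches state markedly
less often than the naive argmax (131 vs 212 transitions in the printed
run) — steadier control at some cost in reaction speed.

Other examples: `01_simulate_stream.py` (stream geometry),
`02_feature_pipeline.py` (queue/filter/RMS), `05_outputs_and_cursor.py`
(interpolation, rate-limited emission, cursor).

A thin CLI mirrors the record → train → validate flow on saved sessions:

```
myodecode simulate --out sessions/ --seed 1
myodecode train sessions/ --out decoder.joblib
myodecode validate decoder.joblib --out report.json
```

Sessions are stored as raw little-endian int16 (`.bin`, channel-major
per window) plus a JSON sidecar; the wire framing for streamed windows
is a uint32 length prefix followed by the 1152-byte payload.

## Scope

The package decodes; it does not render. Graphics, device drivers
(amplifier, prosthesis, orthosis), deep regression models and game
integrations are out of scope; the classifier backend and output sinks
are interfaces so such components can be plugged in.
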