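# Methods

This note documents the models, defaults and numerical choices behind
`emgkit`, and what the synthetic benchmark does and does not establish.

## Signal model (emgkit.synth)

Surface EMG during a held static gesture is, to a good approximation, a
band-limited stochastic carrier whose envelope is set by the contraction
level. The generator models exactly that and nothing more: per channel and
per trial it draws white Gaussian noise, band-passes it to 20–450 Hz
(4th-order Butterworth, zero-phase, the conventional sEMG energy band),
rescales the filtered carrier to unit RMS, and multiplies by the gesture's
per-channel activation amplitude and a trapezoidal envelope with linear
onset/offset ramps (default 200 ms). Trials are separated by rest gaps
(default 500 ms, label −1) and white sensor noise is added over the whole
recording at a configurable SNR.

Definitions and conventions:

- **SNR**: `20·log10(clean-signal RMS / additive-noise RMS)`, both taken
  over the entire recording. `snr_db=inf` disables sensor noise. If the
  clean signal is identically zero (all-rest recordings), the noise
  amplitude is referenced to 1.0 arbitrary unit so that a noisy-rest
  recording is still non-degenerate.
- **Units**: amplitudes are arbitrary units. Real hardware reports mV, but
  no gain calibration is modelled, and nothing downstream depends on the
  absolute scale (features are min–max normalized before classification).
- **Benchmark** (`make_benchmark`): defaults mirror the acquisition
  protocol the decoder targets — 9 gestures on 6 channels, two series
  (learning and testing), each performing every gesture once for 2 s in a
  seeded random order, 20 dB SNR. Gesture profiles are drawn uniformly on
  [0.15, 1.0] per channel and rejection-sampled to a pairwise separation of
  at least 0.4, roughly 3× the standard error of a 200-sample RMS estimate
  accumulated over six channels, so that profiles are resolvable by the
  windowed features. More gestures than 2^K triggers a resolvability
  warning.

Not emulated: motor-unit action potentials, electrode–skin impedance,
crosstalk structure, movement artifacts, fatigue drift, inter-subject
variability. A green benchmark test therefore establishes that the
*pipeline* recovers amplitude-coded gesture structure at realistic SNR; it
says nothing about accuracy on human recordings.

## Features (emgkit.features)

Windows are `[kM, kM+N)` for k = 0, 1, …, so the window count is exactly
`floor((T−N)/M)+1` for every T, N, M; with the default N = 200, M = 100 the
window end times are 200 ms, 300 ms, … as in the classic overlapping-window
scheme. A recording shorter than one window yields zero windows plus a
warning (streaming start-up), not an error.

Window labels are the majority per-sample label, ties resolved by the label
at the window end (deterministic and causal). Rest-majority windows stay in
the stream — the control loop emits one event per window — but are excluded
from classifier training sets by default.

The window step is configurable because the feed rate of the original
design is ambiguous between 100 ms and 50 ms; 100 ms is the canonical
default here.

## Classifier (emgkit.mlp)

A fully connected sigmoid network; default architecture 6 → 8 → 9 (two
trainable layers, selected by the architecture sweep). Choices the
underlying design left open, made explicit here:

- **Bias**: each neuron gets a bias weight on a constant-1 input.
  `bias=False` reproduces the literal bias-free neuron (decision surfaces
  through the origin).
- **Loss**: per-sample squared error L = ½·Σ(y−t)² against one-hot
  targets — the canonical companion of the update rule Δw = η·δ·x, which
  the implementation reproduces exactly (verified against central-difference
  gradients to 1e−6 relative error).
- **Update mode**: per-sample (stochastic) updates in a freshly shuffled
  order each epoch; η = 0.01 by default; weights initialized uniform on
  [−0.5, 0.5] from an explicit seed.
- **Normalization**: features are min–max scaled to [0, 1] with bounds
  computed on the training set only and stored with the model; constant
  features map to 0.
- **Decision rule**: winner-take-all over output neurons, ties to the
  lowest class index; no rejection threshold by default.

**Early stopping.** "Stop when the test error starts increasing" is made
precise as patience-based stopping (default patience 50 epochs, cap 5000)
with best-weights restoration at the epoch of lowest test classification
error. One subtlety matters: the misclassification rate moves in steps of
1/n_test and sits on plateaus lasting well over 50 epochs early in training
at η = 0.01, so patience on the classification error alone halts training
at a fraction of its attainable accuracy (observed: stop near epoch 75 at
~68 % error on the default benchmark, versus ~1 % error when training
continues). An epoch therefore counts as progress if *either* the test
classification error reaches a new minimum *or* the continuous test
squared-error loss makes a new best; stopping fires once both monitors have
stalled for `patience` consecutive epochs. With the defaults this yields
training runs on the order of thousands of epochs, consistent with how this
class of network is known to behave on this task.

## Control (emgkit.control)

The translator is a graph of input, processing and executor modules; the
only legal edges are input→processing and processing→executor, one output
may fan out to several input slots, and each input slot accepts one edge.
Validation reports all violations rather than throwing. Executor modules
are virtual: they carry the pattern→command library and the command log
stands in for a device SDK, which makes the full loop testable.

- **Proportional speed**: `100·clamp((MAV − MAV_rest)/(MAV_max −
  MAV_rest), 0, 1)`. "Proportional" alone does not fix a scale; affine
  mapping between calibrated rest and maximum-effort MAV anchors is the
  standard myocontrol choice. No smoothing is applied (one value per
  window); rapid command alternation is forwarded verbatim and debouncing
  is left to deployments.
- **Hybrid control**: within each window the classified pattern selects the
  command and the MAV sets its speed; there is no further arbitration. A
  pattern absent from the library maps to an explicit `no-op`.
- **NP index**: `NP = ln(E_i/E_1)` per session, exactly 0 on day one.
  Zero-error sessions are clamped to half of one misclassified window,
  `1/(2·n_test_windows)`, before the log-ratio — this keeps NP defined
  while preserving session ordering.

## Experiments (emgkit.experiments)

The architecture sweep grids over depth, hidden width and learning rate,
training each cell on freshly generated benchmarks across seeds and
reporting mean ± sd errors; the cell minimizing mean test error is flagged.
The multi-day progression emulates subject learning by raising the
generator SNR a fixed number of dB per day (default 3), retraining daily
and reporting NP relative to day 1; the benchmark seed is held fixed across
days so a zero effect gives exactly NP = 0 every day.

## Known limitations

- The generator codes gestures purely in per-channel amplitude; spectral or
  temporal gesture signatures are out of scope, so feature sets beyond
  RMS/MAV cannot be meaningfully evaluated on it.
- Per-sample training is O(epochs × samples) in Python/NumPy; the default
  benchmark trains in tens of seconds per seed on one CPU, which is fine
  for its size but not for large feature sets.
- The virtual executor logs commands; it does not model device latency or
  transport loss.
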