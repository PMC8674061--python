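# Methods

## The task and the data model

The pipeline classifies single EOG trials into eleven eye-movement
tasks for a multi-state human-computer interface. A trial is a
100-sample, two-channel (horizontal, vertical) window sampled at
100 Hz. Eight tasks are intentional commands ("events"): right, left,
up-right, down-right, up-left, down-left, rapid (vertical) movement,
lateral movement. Three are non-events: open, close, stare. A subject
contributes 10 trials per task, 110 trials in all.

No public recordings exist for this protocol, so the package ships a
first-class synthetic generator. Templates follow standard EOG
morphology: saccades are step deflections of the corneo-retinal dipole
(rightward gaze → positive horizontal, upward → positive vertical;
oblique movements project ≈ 1/√2 on each channel), lid closure is a
biphasic vertical spike, opening a small rebound bump, stare is
baseline. Trial-to-trial variability is additive white Gaussian noise
(`noise_sd`) plus an optional fixed-phase mains cosine
(`mains_amplitude`, 50 Hz).

**Why the directional templates differ in duration.** The feature
below is quadratic in the signal, so it cannot distinguish a waveform
from its negation: pure mirror-image step templates for right vs. left
would be mathematically inseparable however the classifier is trained.
Cued gaze protocols in practice vary in hold/return timing, so each
directional task is given a distinct gaze-hold profile (sustained step
vs. return-to-center pulses of distinct widths, 0.25–0.6 of the
window). Class identity is therefore carried by temporal structure the
feature can resolve. This is the one place where the generator is
shaped by the feature's algebra, and it is the main caveat when
carrying conclusions to real data: with real recordings the separation
of mirror-image saccades rests on whatever timing/shape asymmetries the
subject actually produces.

What the generator does not emulate: electrode drift and baseline
wander, amplitude variability across repetitions, saccade latency
jitter (templates are deterministic; with `noise_sd = 0` repeated
trials are bit-identical by design), overshoot, crosstalk between
channels, or any subject-specific idiosyncrasy. Passing tests on
synthetic subjects therefore demonstrate that the pipeline recovers a
learnable class structure under calibrated noise — not field
performance.

Determinism: one RNG stream per subject derived from
`(seed, crc32(subject_id))`, split per trial by counter, so trial *i*
never depends on how many trials precede it and datasets regenerate
bit-identically.

## Preprocessing

A 50 Hz notch precedes band splitting. At the protocol rate (fs =
100 Hz) 50 Hz sits exactly at Nyquist, where an IIR notch is
degenerate; the notch there reduces to zeroing the Nyquist bin of the
real FFT. Below Nyquist a standard IIR notch (Q = 30) is applied
forward-backward. The band splitter uses 4th-order Butterworth
band-passes at (0.1–2), (2–4), …, (14–16) Hz, applied with
`sosfiltfilt` (zero phase; padding capped at len−1 for the 100-sample
windows). The 0.1 Hz lower edge of band 1 keeps DC drift out. Filter
coefficients are cached per configuration, so a given config always
yields identical coefficients.

Band-edge behaviour on 1-s windows is transient-dominated for the
narrow bands; the steady-state properties (≥ 20 dB mains attenuation,
in-band energy concentration ≥ 5× any other band) are verified on
10-s test tones.

## Feature

Per band b and channel j, with R the time reversal of the band signal
X:

    f(X) = Re Σ_k F(X)[k] · F(R)[k] = N Σ_n x[n] x[(n+1) mod N],

the right-hand closed form following from the DFT reversal identity
(F(R)[k] = e^{2πik/N} conj(F(X)[k]) for real x) and Wiener–Khinchin.
The closed form is used as an independent oracle in the tests, never as
the implementation path. The statistic is analytically real; the
imaginary residual is asserted below 1e-9 (relative). It is invariant
to circular shifts and scales quadratically.

16 features per trial (channel-major: horizontal bands 1–8, vertical
bands 1–8) are min-max normalized per feature to [0, 1]. The
normalizer is fitted on the training split only (configurable to
`all`); test values outside the training range are clipped; a
degenerate feature (max = min) maps to 0.5.

## Classifiers

Both networks are 16-8-4 with logistic sigmoid hidden and output units
(outputs must live in (0,1) to match the targets). Classes are coded
as the 4-bit binary of the task index (MSB first; 11 distinct codes);
decoding takes the nearest code by Euclidean distance, ties to the
lowest index. Weights initialise uniform(−0.5, 0.5)/√fan-in, seeded.

**Elman network (ERNN).** hidden(t) = σ(W_in x(t) + W_ctx c + b),
context c = previous pattern's hidden activations, reset at epoch
start; gradients treat the context as a constant input (truncated
Elman gradient — verified against central finite differences to 1e-4
relative). Training is batch gradient descent on MSE with momentum
(0.9) and an adaptive learning rate starting at the configured .001
(×1.05 after an improving epoch; step rejected and rate ×0.7 when the
error grows by > 4%). A plain fixed-rate mode (`adaptive_lr=False`)
exists; at a fixed .001 the network cannot reach the 0.001 error goal
within the 1000-iteration cap even on one pattern, so the adaptive
schedule — the common default for Elman training — is the package
default. Patterns are presented in a stratified-shuffled order each
epoch.

**Time-delay network (DTDNN).** Feedforward 16-8-4 with tap delay
lines (default taps 0,1,2) on the input and hidden layers, run across
the within-subject pattern sequence; trained by Levenberg–Marquardt on
the exact Jacobian unrolled over the delay window (the hidden layer
has no recurrence, so the unrolled Jacobian is exact). Damping starts
at 1e-3, ×10 while a step fails to reduce the error, ÷10 on
acceptance; a singular system raises the damping; training reports if
damping exceeds 1e10.

Both stop when the epoch MSE falls below 0.001 or at 1000 iterations;
a non-finite error raises a divergence error with the iteration index.

**Evaluation protocol.** ERNN evaluates a batch with the context reset
at batch start and then carried across patterns in row order. For the
DTDNN the default is the steady-state response: every tap of a delay
line is filled with the pattern under evaluation, which is
order-independent and matches deployment, where each command is
classified alone. Sequential batch evaluation is available
(`dtdnn_eval="sequential"`), but couples each prediction to unrelated
neighbouring trials and measurably degrades held-out accuracy.

## Splits, accuracy conventions, metrics

Splits are stratified per task with a seeded shuffle: ceil(0.75·10) =
8 train / 2 test per task (88/22), with the training share capped at
n−1 so one trial per task is always held out. Per-run headline
accuracy is scored over all 110 trials of the subject — the convention
of the reference accuracy tables, whose entries are multiples of
1/110 — while the held-out-only accuracy is reported alongside
(`extra.mean_test_accuracy`). The "testing error tolerance 0.1"
reading of correctness (every output neuron within 0.1 of its target
bit) is also reported.

Single-trial analysis is the per-task accuracy over that task's 10
trials (multiples of 10%), computed from the first repeat's
predictions over all 110 trials. Confusion counts follow the
event/nonevent bookkeeping: correct event → TP, incorrect event → FP,
correct nonevent → TN, incorrect nonevent → FN; a conventional
one-vs-rest mode exists but is off by default.

Bit transfer rate uses n = 11 selectable movements and an action
period of T_act = 2 s by default. T_act is not stated with the
reference tables; back-solving the BTR formula against all 40
published rows is consistent only with T_act = 2 s and n = 11, and the
recomputation matches every printed BTR within 0.05 bits/min (the
published means are rounded to 2 dp). p·log2 p terms with p = 0 are
taken as 0; p_a at exact chance (1/n) returns exactly 0 bits.

## Calibration and problem sizes

`noise_sd` defaults to 0.05 (deflection amplitude 1.0), calibrated
once so that the Elman classifier operates at 85–95% held-out accuracy
on default synthetic subjects (measured mean 89.1% over seeds 1–5);
the DTDNN reaches ≈ 84% under the same conditions. The calibration is
recorded here and in the generator config, not hard-coded into tests.

Test-suite problem sizes: one synthetic subject (110 trials) per
training run; five seeded subjects for the accuracy property; pipeline
determinism is exercised with 1 subject × 2 repeats × 2 architectures.
Filter steady-state properties use 10-s test tones. These sizes keep
the full suite under a minute of training time while leaving every
property at full protocol scale (110 trials, 16 features, 16-8-4
networks).

## Known limitations

- The quadratic feature's sign-blindness (above) is inherent; the
  synthetic templates are designed so the classes remain separable.
- LM on 88 patterns with ~500 parameters reaches the error goal and
  overfits; the held-out DTDNN accuracy trails the ERNN accordingly.
- The notch at fs = 100 Hz removes only the exact Nyquist component;
  mains leakage into sidebands is not modelled.
- Reports exclude wall-clock timings (logged instead) so that reruns
  are byte-identical; the timing columns of the report tables are
  informational and default to 0.
- Whether band splitting should precede trial segmentation cannot be
  decided from the protocol description; the package filters the
  segmented 100-sample window. Filtering a continuous record first and
  segmenting after is an untested configuration.
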