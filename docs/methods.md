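# Methods

## Problem setting

The package targets screening-grade detection of Parkinson's disease (PD)
from triaxial accelerometer traces recorded by a smartphone during phone
calls, in a cohort restricted to subjects whose self-reported tremor is
minor or absent (UPDRS part II item 16 ≤ 1; items 20/21 are the
clinician-rated rest and action/postural tremor scores carried along in the
metadata). The unit of classification is a one-second window of the
conditioned signal; subject-level labels (pd_status ∈ {0, 1}) are
propagated to every window of that subject's calls.

## Signal conditioning

Phone accelerometer clocks are irregular in the wild, so conditioning is:
(1) if the timestamp grid is non-uniform, linear interpolation onto the
native nominal rate; (2) Butterworth low-pass at 12 Hz (order 4 by default,
applied forward–backward so the effective magnitude response is
|H(f)|² = (1 + (f/f_c)^(2n))⁻¹ squared once more and the phase is zero);
(3) polyphase resampling to 100 Hz. Filtering precedes decimation so the
rate change cannot alias; because 12 Hz is below the output Nyquist of
50 Hz, the result is equivalent to filtering after downsampling. Rest
tremor is informative only up to about 12 Hz, which is why 100 Hz sampling
and a 12 Hz cutoff lose nothing of interest. Zero-phase filtering is a
deliberate choice: it keeps window boundaries aligned with the physical
events, at the price of being non-causal (irrelevant offline). Input unit
is m/s²; a `g` flag converts on load. Calls shorter than one window after
conditioning are dropped and counted.

## Feature definitions and conventions

Windows are 100 samples (1 s) with 50% overlap; the window count for a
length-L call is floor((L−100)/50) + 1 and trailing samples are discarded.
The 33-vector per window decomposes as 18 + 1 + 3 + 9 + 2:

- Per-axis statistics (max, min, mean, std, kurtosis, skewness for x, y,
  z) use population (divisor-N) moments; kurtosis is excess (−3).
- The zero-crossing rate and all spectral features are computed on the
  Euclidean magnitude √(x²+y²+z²) with its window mean removed — the
  magnitude is orientation-invariant, and mean removal gives the sign
  changes a zero-crossing rate needs.
- The PSD is a one-sided Hann-tapered periodogram over the whole window
  (51 bins at 1 Hz spacing). Welch sub-segmentation is pointless inside a
  100-sample window and is not used; the estimator/taper are configurable.
- Spectral rolloff is the smallest frequency below which ≥ 85% of total
  PSD lies. Spectral flatness is the geometric-to-arithmetic PSD mean
  ratio. Spectral entropy is Shannon entropy (bits) of the PSD normalised
  to a probability vector. Spectral skewness/kurtosis are the PSD-weighted
  third/fourth central moments of frequency about the spectral centroid,
  normalised by the PSD-weighted std of frequency; kurtosis is excess.
- Degenerate inputs have fixed conventions so no NaN ever reaches the
  model: zero-variance axes get std/kurtosis/skewness/correlation 0; an
  all-zero window gets a zero spectral block; zero PSD bins are floored at
  1e-12 inside logarithms.

The feature order (`FEATURE_NAMES`) is part of the model contract, because
the classifier consumes the vector as a sequence.

## Classifier

The network is the stack described in the README (three bidirectional LSTM
layers of 32/64/128 units with concatenation merge, dropout 0.2 after each,
parameter-free attention, flatten, sigmoid dense head; 346,369 trainable
parameters in total). It is implemented in numpy in float64 — forward pass,
backpropagation through time, Adam and binary cross-entropy — with no
framework dependency; gradients are validated against central differences
in the test suite.

Design points that were genuinely open:

- **Merge mode.** Concatenation is the default because the published layer
  widths (64/128/256) and parameter counts are only consistent with it. An
  averaging merge — tanh read-outs of each direction's hidden state,
  averaged — exists as a documented, forward-only variant.
- **Attention.** The default attention is parameter-free and
  shape-preserving: the query is the temporal mean of the sequence, scores
  are dot products with the query, weights are the softmax over time, and
  each timestep is rescaled by T·α_t so uniform attention is the identity.
  This matches an attention layer with zero parameters and unchanged
  (33, 256) output followed by an 8448-wide flatten. The classical learned
  attention (scores vᵀtanh(W·h_t + b), pooling to a context vector
  Σ_t α_t h_t) is implemented and oracle-tested as a variant; it has
  parameters and changes the downstream shape, so it is not the default.
- **Initialisation** (unspecified upstream): Glorot-uniform input weights,
  per-gate orthogonal recurrent weights, zero biases except the forget
  gate at 1.0; all seeded, so forward passes are bitwise reproducible with
  dropout off.
- Dropout rates are unstated upstream; 0.2 everywhere, configurable.

Training uses Adam at learning rate 1e-4 with minibatches of 128 and early
stopping on validation loss (patience 3, best-validation weights
restored); the classification threshold is 0.5. `max_epochs` defaults to
100 with early stopping governing in practice.

## Evaluation protocol

The 70/30 train/test split and the fivefold cross-validation are
stratified by label; |test| = round(0.3·n) exactly. The default split unit
is the *window*, mirroring the original protocol. This has a known and
deliberate caveat: 50%-overlapping windows from the same call (which share
half their samples, plus call-level constants such as the gravity
projection in the per-axis means) can land on both sides of a split, so
window-level metrics partly reflect call memorisation, not only tremor.
A subject-level split (`split_unit="subject"`, greedy per-class packing to
the target fraction, no subject on both sides) is provided and is the
right instrument whenever the question is generalisation to unseen people;
the package's own null-calibration check uses it for exactly that reason.
Zero-denominator metrics are reported as 0 and flagged. The trapezoid-rule
AUC over the threshold sweep is algebraically the normalised Mann–Whitney
U statistic, and the test suite asserts that identity.

## Synthetic cohorts

Each simulated call is gravity (9.81 m/s² along a random fixed orientation
per call) + band-limited voluntary drift (0.1–2 Hz, 0.05 m/s² RMS per
axis — the hand holding a phone to the ear is relatively still) + white
sensor noise (sd 0.1 m/s², a plausible phone-MEMS noise floor over a
100 Hz bandwidth) + for PD subjects only, a sinusoid at a subject-specific
frequency drawn from 4–6 Hz, projected on a random axis, with a slow
sinusoidal amplitude envelope (depth 0.5, 0.2 Hz) emulating tremor waxing
and waning. Controls have exactly zero tremor amplitude, so class
differences are confined to the tremor component by construction.

Default cohort: 22 PD / 14 HC subjects, 2 calls × 10 s each at a native
200 Hz (→ 1368 windows), tremor amplitude 0.3 m/s² = 3× the noise sd.
These sizes keep a full train/evaluate cycle to a few minutes on one CPU
while leaving the task non-trivial; the drift and noise scales were set so
that a tremor of 3× the noise sd is clearly detectable in the features —
the operating regime the pipeline is designed for — rather than buried
under voluntary motion. A `null_cohort_config()` preset gives a
class-balanced (14/14), tremor-free cohort: balance makes chance level 0.5
so a binomial band around it is a meaningful no-leakage calibration. An
8 PD / 13 HC configuration mirrors the smaller tremor-unaware (updrs16 = 0)
sub-cohort, and `pd_updrs16` switches the PD subjects' self-report score.

What the generator does *not* emulate: biomechanics of the arm, gyroscope
channels, hardware-specific noise spectra, non-stationary carrying states
(walking, typing), co-existing bradykinesia, or between-subject severity
heterogeneity. Passing tests on synthetic cohorts therefore demonstrate
that the pipeline recovers a 4–6 Hz oscillatory class difference of the
stated magnitude under realistic noise and drift — not that the published
real-cohort performance transfers.

## Known limitations

- Window-level splitting inflates metrics on subject-correlated data (see
  above); subject-level results will generally be lower and are the more
  honest generalisation estimate.
- The numpy implementation is single-threaded and CPU-bound; it is sized
  for cohorts of tens of subjects, not thousands.
- The learned-attention and averaging-merge variants are forward-only
  (equation fidelity), not trainable configurations.
- Calls are assumed pre-segmented; no voice-activity or call detection.
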