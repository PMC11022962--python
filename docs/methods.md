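# Methods

This note documents the modelling assumptions, parameter choices and known
limitations of the `dbgcn` pipeline. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from outside.

## Preprocessing

Recordings pass through a cascade of zero-phase filters: a second-order IIR
notch at 50 Hz (quality factor 30, a ~1.7 Hz notch width) against mains
interference, a 0.3–50 Hz band-pass, and a 1–50 Hz fourth-order Butterworth.
The two band-pass stages overlap; applying both (composite passband
effectively 1–50 Hz) follows common depression-EEG protocols, and either
stage can be disabled via `FilterSpec`. All filters run forward–backward
(`filtfilt`), because windowed features must not be time-shifted by group
delay.

Baseline correction subtracts each channel's mean over the first 120 s from
the entire channel — a constant DC correction, not a per-window recentering.
The high-level pipeline clamps the baseline window to the recording length
so that short (synthetic) recordings use their full duration; calling
`baseline_correct` directly with a window longer than the recording is an
error.

Segmentation uses a 4 s window with a 2 s stride (50% overlap), producing
`floor((T − 4)/2) + 1` windows per recording: 60 per 122 s recording, hence
3,180 segments for a 53-subject cohort and 7,140 for 119 subjects.
Recordings shorter than one window yield zero segments with a warning rather
than an exception, so batch runs skip short files; windows are never
zero-padded, since padding would bias the variance that DE estimates.

Montage harmonization (`select_channels`) requires an explicit channel list;
no default subset of a high-density montage is hard-coded. ICA artifact
removal is a pluggable hook (`remove_artifacts_hook`) that validates shape
preservation; FastICA itself is established methodology and deliberately not
reimplemented here.

## Features

Each segment is decomposed with fourth-order Butterworth band-passes into
delta (0.5–4), theta (4–8), alpha (8–12) and beta (12–30 Hz). Differential
entropy is computed per (channel, sub-window, band). The default estimator
is the Gaussian closed form ½ ln(2πe σ²) with σ² the unbiased sample
variance of the band-filtered signal: for a fixed-length band-limited
segment this coincides (up to constants) with the log band energy, it is
exactly +ln c equivariant under amplitude scaling by c, and it is testable
against theory (Monte-Carlo bias < 0.02 at 1,000 samples). A literal
log-power variant, ½ ln P + ½ ln(2πe N), is available behind a flag, as is a
plain log-PSD feature for comparison runs.

The sub-window count is t = 4 non-overlapping 1 s sub-windows per 4 s
segment — 1 s is the common DE convention and divides the window evenly —
giving the BiLSTM a length-4 sequence per channel. Features are z-scored
per (channel, band) with statistics fitted on the training folds only,
preventing train/validation leakage.

## Graph

Edge weights are Pearson correlations of the preprocessed *continuous*
signals, estimated from the concatenation of the training-fold subjects'
recordings (one fixed graph per fold; validation subjects never contribute).
Negative correlations would produce non-positive degrees in the symmetric
normalization, so the default signed-edge policy takes absolute values
(connectivity strength regardless of sign); clipping negatives to zero is
available. No sparsification is applied — the network stays dense.

The propagation operator is S = D̃^{-1/2}(A′ + I)D̃^{-1/2}; the added
self-loop guarantees strictly positive degrees. Pooling halves the node
count per layer via greedy heavy-edge matching on |A|: edges are visited in
decreasing weight with deterministic low-index tie-breaks, matched pairs
merge, a left-over node becomes a singleton, and coarse edge weights are
sums of the fine weights between groups. Node features pool by elementwise
max (mean available). An alternative reading of "spectral pooling" —
truncating graph-Fourier coefficients — was considered and rejected in
favor of node coarsening, which matches the stated halving of node count.

## Model

The per-channel sequences are encoded by a single shared-weight BiLSTM
(default hidden width 16 per direction, so node features have d′ = 32);
the node-feature matrix feeds two graph convolutions of width 32 and 64,
each followed by a bounded ReLU (min(max(x, 0), 6) — "bounded" rather than
"bipolar" ReLU, with the cap configurable) and one 50% pooling step, so a
64-electrode graph coarsens 64 → 32 → 16. The pooled features are flattened,
passed through dropout (rate 0.5, applied only during training, placed
between pooling and the dense layer), and classified by a dense softmax.

The loss is mean cross-entropy (log clamped at 1e-12) plus λ·Σθ² over all
trainable weights and biases, λ = 1e-4 by default. Optionally each sample's
cross-entropy is weighted by the inverse frequency of its class (off by
default; see Cross-validation). Parameters initialize Glorot-uniform from a
seeded generator; biases start at zero.

The implementation is plain NumPy. Gradients are hand-derived —
backpropagation through time for the LSTM, matrix calculus for S·H·W, argmax
routing through max pooling — and checked against central finite differences
(relative error ≤ 1e-3 on sampled coordinates of every parameter array; in
practice ~1e-7).

## Cross-validation and training

Folds are formed over *subjects*: subjects are shuffled by the seed and
split into k ≈ equal validation groups, so no individual contributes
segments to both sides of a fold. Within each fold's training subjects an
inner 90/10 subject split monitors generalization; training runs the full
epoch budget (no early stopping) and keeps the checkpoint with the best
inner accuracy, ties broken toward the later epoch (with a tiny inner set
many epochs share the top accuracy, and the most-trained of them
generalizes best). The default optimizer is Adam; the defaults (100 epochs,
batch 512, learning rate 1e-5) target full-size cohorts with thousands of
segments. Batch size is clamped to the dataset size with a warning.
The per-fold summary reports the sample mean and sample standard deviation
(ddof = 1) of each metric across folds. The depressed class is the positive
class; rates with empty denominators (possible when a tiny fold holds out a
single class) are reported as 0.

## Synthetic data

The generator emulates the second-order statistics the classifier consumes.
Each subject is a sum over the four rhythms of band-limited Gaussian noise
(white noise passed through the same Butterworth band filters the feature
extractor uses, keeping simulator and pipeline spectrally consistent), with

* a 1/f-like control band-power profile (delta 1.0, theta 0.8, alpha 0.6,
  beta 0.4 relative variance; ~10 µV scale),
* the depressed class multiplying delta and theta power by (1 + effect_size),
* channels partitioned into communities sharing a latent signal per band,
  giving within-community correlation 0.3 for controls and
  0.3 + 0.1·effect_size for depressed subjects (both class effects scale
  with effect_size, so effect_size = 0 makes the classes distributionally
  identical),
* a per-channel DC offset (σ = 5 µV) and a 2 µV 50 Hz line-noise sinusoid,
  so baseline correction and the notch filter are exercised.

Correlation is induced by latent-signal mixing
(√(1−ρ)·own + √ρ·community), which guarantees a valid covariance for any
ρ ∈ [0, 1). Per-subject seeds derive deterministically from the dataset
seed and are recorded in a manifest; regeneration is bit-identical.

What the generator does **not** model: dipole/forward physics and realistic
scalp topographies, non-Gaussian transients, 1/f-continuous spectra (power
is piecewise per band), ocular/muscle artifacts, or non-stationarity.
Passing tests therefore demonstrate that the pipeline recovers the class
structure it assumes — class-dependent band power and connectivity — not
clinical performance on real EEG.

## Scaled reference experiments

Full-size training (thousands of segments, 100 epochs, batch 512) is not
needed to validate correctness, so the reference experiments in
`dbgcn.experiments` use scaled study conditions: 20 subjects (10/10),
16 channels, 30 s recordings at 250 Hz, a reduced model (hidden 8, GCN
widths 16/32), 20 epochs, batch 64, subject-wise 10-fold CV. At this scale
80 Adam steps must actually converge, so the scaled protocol uses the
conventional small-model Adam rate 1e-3 (the 1e-5 default belongs to the
full-size regime) and enables inverse-frequency class weights: with
2-subject validation folds, holding out two same-class subjects leaves the
training split mechanically imbalanced against that class, which on
signal-free data would push those folds systematically below chance.
With weighting, the `easy` preset (effect_size 2) reaches mean CV accuracy
1.0 and the `null` preset (effect_size 0) stays near 0.5 across seeds. The
whole battery, including the determinism re-run, completes in ~1 minute on
one CPU.

## Known limitations

* The EDF reader requires the optional `mne` dependency; the plain-text
  matrix + JSON sidecar format needs nothing beyond NumPy.
* Pearson correlation captures only linear, zero-lag coupling; coherence,
  phase-lag and mutual-information connectivity are out of scope.
* Training is single-threaded NumPy: appropriate for the scaled
  experiments and small cohorts, slow for very large grids or montages.
* The checkpoint rule assumes the inner split is informative; with very few
  subjects per class the inner accuracy is coarse (steps of one segment
  share), which the later-epoch tie-break mitigates but does not remove.
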