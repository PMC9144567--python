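# Methods

## Scope and model

somnograph implements an attention-guided spatiotemporal graph
convolutional classifier for 30-s sleep epochs.  The pipeline is:
EDF/EDF+ signals → label harmonization (R&K → AASM, movement/unknown
epochs dropped, peripheral wake trimmed to a 30-min margin) →
per-epoch, per-electrode, per-band differential entropy → temporal
context blocks → ST-GCN stack → softmax stage probabilities.

Modeling assumptions:

* **Gaussianity per band.** Differential entropy is computed with the
  Gaussian closed form DE = ½·ln(2πe·σ²) on the band-filtered epoch,
  using the population variance.  Band-limited EEG over 30 s is treated
  as approximately Gaussian; no empirical-entropy estimator is used.
* **Graph structure.** Electrodes are nodes.  The static adjacency
  comes from physical montage neighborhoods (shipped presets: `isruc6`,
  `sleepedf2`, `generic_10_20`; custom YAML edge lists accepted) and is
  symmetrically normalized with self-loops, D̃^{-1/2}(A+I)D̃^{-1/2}.  A
  trainable additive mask G_m (zero-initialized, so training starts at
  the physical topology) perturbs the *normalized* matrix; the
  alternative conventions are exposed as `static_norm: none|pre|post`
  with `pre` the default.  The dynamic graph is recomputed per frame
  from that frame's node features as a row-softmax of
  relu(wᵀ|x_i − x_j|); a per-sample mean across frames is available via
  `gd_mode: mean`.
* **Stationarity within an epoch.** Features ignore within-epoch
  dynamics; temporal structure enters only through the context window
  (k = 4, d = 1, T_n = 5 by default) and the TCN.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| bands | delta 0.5–4, theta 4–8, alpha 8–13, sigma 11–16, beta 16–30 Hz | DE features per electrode; sigma overlaps alpha/beta deliberately (spindles) |
| k, d | 4, 1 | context: T_n = k+1 epochs, stride d; epochs with t < k·d are dropped, not padded |
| channel plan | (66,66,66,132,132,132,264,264,264) | module output widths; any plan ≥ 7 channels per module is valid (reduced plans for desk-scale runs) |
| φ | 0.5 | static/dynamic fusion weight, constant in [0,1] (not learned) |
| r | 4 | attention squeeze ratio; hidden width = ⌊C/r⌋ |
| dilations | (1,2,3,4) | the four dilated TCN branches |
| dropout | 0.2 | after each module's attention block |
| optimizer | Adam, batch 64, lr 1e-3 ÷10 at epochs 30/60/90, 120 epochs | reference recipe; class-weighted loss available (`inverse`), unweighted by default |

Per-recording z-scoring of DE features (per electrode-band) is on by
default and toggleable; it removes subject- and amplifier-scale
differences before the network.

## Numerical choices

* **Filtering**: 4th-order Butterworth band-pass applied
  forward-backward (`sosfiltfilt`), so the phase is zero and the
  effective magnitude response is squared.  Band edges are validated
  against Nyquist.
* **Zero variance**: a flat band signal would give DE = −∞; it returns a
  configurable floor (−20 nats) and warns.
* **Channel partition in the TCN**: each of the six transform branches
  owns ⌊C_out/7⌋ channels; the residual branch takes the remainder, so
  any plan whose entries are ≥ 7 is exactly covered.
* **Max-pool padding** uses −∞ so edge frames never select padding;
  dilated convolutions use symmetric zero padding, preserving T for any
  T ≥ 1.
* **Attention squeeze ordering** is FC → batch norm → Swish (the
  standard conv-BN-activation pattern); the exact BN position inside the
  block is not fully determined by the architecture diagrams, and this
  choice is recorded here as the package's resolution.  With ⌊C/r⌋ the
  hidden width, plans such as 66 channels at r = 4 are legal (the ratio
  need not divide the width exactly).
* **Ties in max reductions** route gradient equally to all argmax
  positions (symmetric subgradient).
* **Autodiff**: the package ships its own reverse-mode engine on
  float64 numpy arrays.  Every primitive and every composite block is
  tested against central finite differences at 1e-4 relative error
  (with a 1e-4 denominator floor so entries whose true gradient is ~0
  are compared absolutely against finite-difference noise).
* **EDF writing** uses 16-bit encoding with per-channel symmetric
  physical ranges and a quantizer centered on the reader's affine
  convention, keeping round-trip error within half an LSB of each
  channel's range.
* **Degenerate inputs**: all-wake recordings trim to an empty range with
  a flag; context assembly over too few epochs returns an empty set with
  a warning; a non-finite training loss aborts with a diagnostic rather
  than continuing.

## The synthetic generator

The simulator emulates the *structure* of public PSG datasets — 30-s
epochs at 100 or 200 Hz, 2–6 EEG channels, five AASM stages, N2-heavy /
N1-scarce composition — via a first-order Markov hypnogram (sticky N2
and N3, wake entering through N1, REM reachable only from N2; the full
5×5 matrix is user-overridable) and per-stage spectral profiles: W
alpha+beta at low amplitude, N1 theta, N2 sigma+theta, N3 delta at high
amplitude, R theta+beta at the lowest amplitude.  Epochs are sums of
random-phase sinusoids (frequencies drawn inside each band, shared
across channels; phases channel-specific) plus white noise.  All
randomness flows from one seed; equal specs reproduce identical bytes.

What it does **not** emulate: waveform morphology (spindles,
K-complexes, slow-wave shapes), artifacts, EOG/EMG, inter-subject
spectral variability beyond sampling noise, and second-order stage
dynamics.  Consequently, passing end-to-end tests demonstrates that the
implementation can learn stage-discriminative spatial-spectral-temporal
structure — not that it attains clinical-grade performance on real
recordings.  The generator's default profiles are deliberately
well-separated (a linear probe on DE features exceeds 90% accuracy, a
tested invariant), so failures in learning tests indict the network,
not the data.

## Desk-scale evaluation design

Training the full 9-module model on the public datasets is out of scope
for the bundled experiments; instead the learning study uses the default
synthetic dataset (4 subjects × 200 epochs, 6 channels, 100 Hz), a
reduced plan (16, 16, 32), 40 training epochs, and subject-wise
held-out evaluation.  The acceptance script reports held-out accuracy
and the attention on/off macro-F averaged over three seeds.  At this
sample size (~600 training contexts) the ablation contrast carries
substantial seed-to-seed variance — single-seed differences in either
direction are common — so the three-seed average should be read as a
qualitative, not definitive, comparison; both arms' values are reported
rather than a single verdict.

## Known limitations

* The Gaussian DE form understates entropy for strongly non-Gaussian
  epochs (artifacts, movement).
* Only EEG channels are modeled; EOG/EMG fusion, artifact rejection and
  re-referencing are out of scope.
* φ is a fixed constant; learning it (or per-module values) is untested.
* The macro-F default is the mean of per-class F1; the harmonic
  combination of macro-precision and macro-recall is exposed as
  `macro_f_harmonic` because the two diverge on imbalanced matrices
  (both are computed on every report).
* The EDF writer targets EEG-only, single-rate recordings; EDF+
  annotation tracks are read but not written (hypnograms are written as
  TSV).
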