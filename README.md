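# somnograph

Five-class sleep staging (W, N1, N2, N3, R) from multi-channel EEG with an
attention-guided spatiotemporal graph convolutional network, plus the
surrounding tooling a sleep lab needs to exercise it: EDF/EDF+ readers with
hypnogram harmonization, differential-entropy band features, the standard
sleep-scoring metric suite, and a synthetic polysomnography simulator so the
whole pipeline runs and trains without downloading clinical data.

## The problem

Polysomnography is scored by experts in 30-second epochs following the AASM
manual (five stages; the older R&K scheme's S3/S4 merge into N3).  Manual
scoring is slow, and EEG electrodes form a graph, not a grid: each channel is
a node wired to its physical neighbors, while functional coupling between
channels changes from epoch to epoch and stage to stage.  somnograph models
both.

## The model

Each 30-s epoch of each electrode is reduced to differential entropy per
frequency band (delta 0.5–4, theta 4–8, alpha 8–13, sigma 11–16, beta
16–30 Hz),

&nbsp;&nbsp;&nbsp;&nbsp;DE = ½ · ln(2πe·σ²)  (nats),

giving an N × F_de feature matrix per epoch.  A temporal context
C = [X_t−kd, …, X_t] ∈ R^{N×F_de×T_n} of T_n = k+1 epochs is classified
with the stage of its final epoch.  The network stacks ST-GCN modules
(default plan 66, 66, 66, 132, 132, 132, 264, 264, 264), each of which:

1. **Spatial step.** Two graph convolutions per frame: a *static* branch
   λ((G_p + G_m)·X_t·μ) over the normalized physical adjacency G_p plus a
   trainable mask G_m, and a *dynamic* branch G_d·X_t·μ′ over a per-sample
   graph whose edges score feature dissimilarity,
   G_d(i,j) ∝ softmax_j relu(wᵀ|x_i − x_j|).  The branches fuse as
   `dynamic + φ·static` (φ ∈ [0,1], default 0.5).
2. **Temporal step.** A seven-branch multi-scale TCN: four 3×1 dilated
   convolutions (dilations 1–4) behind 1×1 bottlenecks, a 1×1 within-frame
   branch, a 3×1 max-pool branch, and a residual branch, concatenated on the
   channel axis.
3. **Attention.** An inter-temporal block max-pools over frames and over
   electrodes, squeezes the concatenated descriptors through a shared FC
   (ratio r = 4, batch norm, Swish), re-expands with two independent
   sigmoid-gated FCs, and reweights the input with the per-channel outer
   product of frame scores and electrode scores.  The block can be ablated
   with `attention: false`.

A global-average-pool + linear + softmax head emits stage probabilities.
Training follows the reference recipe: Adam, batch 64, lr 1e-3 stepped ÷10
at epochs 30/60/90, dropout 0.2, 120 epochs, subject-wise cross-validation.

The network is built on a small reverse-mode autodiff engine
(`somnograph.autodiff`) written for this package; every layer's gradients
are validated against finite differences in the test suite.

## Worked example

Score any labeled 5×5 confusion matrix (rows = actual, columns = predicted,
order W/N1/N2/N3/R).  On the bundled sleep-EDF benchmark matrix:

```bash
$ somnograph metrics --confusion tests/data/sleep_edf_confusion.tsv
{
  "accuracy": 91.0,
  "macro_precision": 87.4,
  "macro_recall": 90.9,
  "macro_f": 89.0,
  "macro_f_harmonic": 89.2,
  "kappa": 0.88,
  "per_class": {
    "W":  {"precision": 91.3, "recall": 93.0, "f1": 92.1, "support": 7927},
    "N1": {"precision": 72.2, "recall": 89.0, "f1": 79.7, "support": 2804},
    ...
}
```

Accuracy is trace/total; macro precision/recall are unweighted class means;
`macro_f` is the mean of per-class F1 (see `docs/methods.md` for why this is
the default rather than the harmonic combination, which is also reported);
κ = (p_o − p_e)/(1 − p_e) corrects agreement for chance.  The 79.7 N1 F1
illustrates the well-known difficulty of the N1 transition stage.

End to end on synthetic data:

```bash
$ somnograph simulate --out demo/ --subjects 4 --epochs 200 --seed 7
$ somnograph extract-features --edf demo/synthetic-00.edf \
      --hypnogram demo/synthetic-00.tsv --out demo/feats.tsv --no-trim
wrote 200 epochs x 6 channels x 5 bands -> demo/feats.tsv
$ somnograph train --data demo/ --out demo/model.npz --epochs 40 \
      --test-subject 3
$ somnograph evaluate --model demo/model.npz --data demo/
```

The feature TSV holds one row per epoch with per-electrode, per-band DE
values in nats (e.g. an N3 epoch shows its largest DE in the delta column).

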