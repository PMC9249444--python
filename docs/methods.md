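# Methods

This note records the model, the choices that were genuinely open when
the package was designed, and what the synthetic benchmark does and
does not establish.

## Signal model and preprocessing

Input records are single-lead ECG streams in mV with beat annotations
(sample index of the R point, symbol).  Annotation symbols are grouped
into the AAMI superclasses N (normal and bundle-branch), S
(supraventricular ectopic) and V (ventricular ectopic); fusion and
paced/unknown beats are excluded and counted, since the classifier only
models the three reported classes.

Denoising decomposes the whole record into nine wavelet scales (db6 by
default), soft-thresholds all detail coefficients with the universal
threshold `σ̂·√(2 ln N)·threshold_scale`, where `σ̂ =
median(|d₁|)/0.6745` is estimated from the finest detail level, and
reconstructs by the inverse transform.  `threshold_scale` (default 1)
is the single denoising knob; 0 turns the step into the identity, which
is how the transform round trip is tested.  Baseline wander is removed
by zeroing the level-9 approximation band — at 360 Hz that band ends
near 0.35 Hz, comfortably below the heart rate.  Periodization is used
at the boundaries, so a non-periodic drift leaves wrap-around residue
in the outermost samples; interior samples are cleaned essentially
exactly.

Segmentation takes the annotations as given (no R-peak detection): one
250-sample window per annotation, 100 samples before the R point and
150 after, covering QRS and T at 360 Hz.  Records at other rates are
polyphase-resampled to 360 Hz with annotation indices rescaled.
Windows that cross a record boundary are dropped and reported, never
silently padded.  Each slice is scaled to unit L2 norm; the order
denoise → segment → normalize is fixed.

## Feature extractor

Each slice is cut into ⌈r/ω⌉ windows of ω = 25 samples (the last
window edge-padded), every window is encoded by one shared first-level
recurrent cell (its final hidden state is the window summary), and a
second-level cell encodes the summary sequence; a linear map plus tanh
produces the m = 64 feature vector.  Weight sharing across windows is
what makes the model micro: the parameter count is independent of the
slice length, and the default model serializes to well under 1 MB.

Three choices here came out of experiments with the synthetic task and
are worth recording:

* **Cell type.**  The architecture accepts plain RNN, GRU, LSTM or
  BiLSTM cells.  Unidirectional cells at random initialization are
  contractive: information from early windows has mostly decayed from
  the final state, and the N/S distinction — the presence of the P
  wave, which sits in the earliest windows — does not survive to the
  feature (N–S feature gap ≈ 0.6× the within-class spread).  The
  default is therefore BiLSTM, whose backward scan reads the beat onset
  last (gap ≈ 4× the within-class spread).  Gate biases are initialized
  at +1 (GRU update gate, LSTM forget gate) so the scan retains
  early-window information — the usual "remember bias".
* **Input gain.**  Unit-L2 slices of length r have per-sample RMS
  1/√r ≈ 0.06, too small to move a recurrent cell away from its
  bias-driven fixed point.  Inputs are scaled by √250 ≈ 15.8 (the
  default slice length), restoring O(1) sample amplitude.  The gain is
  a fixed configuration constant, not data-dependent, so the
  window-split/encode composition stays exact.
* **Frozen extractor.**  The one-class losses give the extractor only
  one signal — "raise every scorer's output" — whose cheapest solution
  maps all beats to a single feature point; joint training was observed
  to collapse the feature variance and the ensemble to chance.  By
  default the seeded extractor is therefore kept fixed (a randomly
  initialized BiLSTM already separates the synthetic classes) and only
  the scorers are trained; `TrainConfig(train_extractor=True)` restores
  the joint path for experimentation.

## One-class scorer bank

Scorer i is the bias-free three-layer perceptron
`f_i(F) = W₃·σ(W₂·σ(W₁·F))` (σ = tanh on the hidden layers; the σ in
the loss is the logistic sigmoid — the two play different roles and
must be distinct for `−log σ(f)` to be a valid loss).  Bias-freedom is
load-bearing: with a free output bias the loss below is minimized by
pushing the bias up while the gradient penalty shrinks every weight,
leaving a constant scorer and a meaningless cross-class argmax.

Training classifier i uses only class-i features (no negative
sampling):

    loss_i = E[−log sigmoid(f_i(F))] + η·E[‖∂f_i/∂F‖₂^c] + π·‖θ_i − μ*‖₂²

* The NLL pushes the own-class score up.
* H-reg, the expected c-th power of the input-gradient norm, bounds how
  fast the score can grow anywhere, balancing the NLL.  For the
  three-layer perceptron the input gradient has the closed form
  `((w₃ ⊙ s₂′)W₂ᵀ ⊙ s₁′)W₁ᵀ`, which is built from ordinary graph
  operations so that plain first-order backpropagation differentiates
  the penalty with respect to the weights — no second-order machinery.
* The anchor keeps scorer i near `μ*`, the arithmetic mean of the
  previously initialized scorers' parameter vectors, holding the bank
  in one region of parameter space so that raw scores are comparable.
  During training the mean is recomputed from the current (detached)
  parameters of scorers 1..i−1 each step, a live anchor rather than one
  frozen at initialization.

Scorers are initialized sequentially: scorer 1 at random, scorer i > 1
at the mean of its predecessors plus a small perturbation (sd 0.01) to
break symmetry.

**Feature centering and whitening.**  Scores are computed on
`W·(F − F̄)`, where `F̄` is the training-set mean feature and `W` a
shrinkage-regularized ZCA whitening matrix fit on the training
features; both are stored in the model.  Centering matters because the
large common component of the features acts through each scorer as an
arbitrary constant offset (`w_i·F̄`) that differs between scorers and
swamps the class-specific response.  Whitening matters because the
between-class axes are wildly anisotropic: the ventricular class sits
far from the other two, so the centered N and S cluster means are both
dominated by the shared "not-V" direction and the small N/S
differential — the quantity the argmax must resolve — is second-order.
Equalizing the axes (`W = V·diag(1/√(λ + 0.1·λ̄))·Vᵀ` from the
eigendecomposition of the feature covariance; the shrinkage bounds the
amplification of low-variance noise directions) puts all class pairs
at comparable scale and makes the one-class bank reliable across
seeds.  Both are standard front-end standardization steps applied at
the classifier head.

**Shared-knowledge removal.**  Modeling scorer i's parameter posterior
as an isotropic Gaussian `N(θ_i, σ²I)`, the distribution minimizing
`Σ φ_i KL(P_i ‖ P)` over Gaussians is moment-matched with mean
`ρ* = Σ φ_i θ_i` (σ cancels).  After training, every scorer is shifted
once by `θ_i ← θ_i − τ·ρ*` (τ = 0.1, φ uniform), trimming the common
parameter component the scorers share.  The step is deliberately not
idempotent; it is applied exactly once, after the best-validation
parameters are restored and before evaluation.  τ near 1 would remove
the entire common component — destructive when the scorers are similar,
since the remaining deviations no longer span a working network — so
the default keeps the step small.

**Prediction** is `argmax_i f_i(F)` with ties broken toward the lowest
class index (plain argmax); classes are ordered N, S, V.

## Training protocol

Stratified 6:2:2 split with largest-remainder rounding: the three
global sizes are exact (100 beats → 60/20/20) and per-class proportions
are within one beat of the fractions.  Each optimization step draws one
batch per class (batch 32), computes each scorer's one-class loss on
its own class's features and sums them; Adam with lr 10⁻³ runs for 30
epochs.  The spec-level knobs are η = 1, c = 2, π = 0.1, τ = 0.1,
scorer hiddens 32/16.  Validation accuracy (argmax prediction) is
evaluated each epoch and the best parameters are retained — this matters
because prolonged one-class training slowly homogenizes the scorers;
the validation set picks the epoch where they are most distinct.  All
randomness (init, shuffling, perturbations) derives from one seed, and
two runs under the same seed are bit-identical.

Metrics are percent-scale: per-class precision TP/(TP+FP), recall
TP/(TP+FN), F1 as the harmonic mean, overall accuracy as the confusion
trace over the total.  Classes with no predicted positives report
precision 0 and are flagged.  The confusion matrix itself comes from
scikit-learn; the derived metrics are computed in-package and
cross-checked against scikit-learn in the tests.

## Synthetic benchmark

The generator renders beats as sums of five Gaussian deflections
(P, Q, R, S, T) on a linear time grid — the standard Gaussian-wave ECG
morphology model without limit-cycle dynamics.  Class templates: N has
the full P-QRS-T complex; S lacks the P wave and has a 10% narrower
QRS; V lacks the P wave, has a 2.5× wider QRS and an inverted T wave.
Records place beats at truncated-normal RR intervals (mean 0.8 s, sd
0.05 s, floor 0.4 s so beats cannot overlap) and add baseline wander,
powerline hum and white noise per the noise spec; per-beat morphology
jitter is multiplicative log-normal with sd 0.05, enough within-class
variance to make learning nontrivial.  `make_dataset(separation=s)`
interpolates the S template linearly toward N, so s = 0 makes N and S
identical and small s reproduces the confusable-class regime where
N/S errors dominate.

The default benchmark (200 beats per class, separation 1) reaches
≥ 90% test accuracy — in practice 100% on every seed we ran — within
seconds on one CPU.
What this shows: the whole chain — segmentation geometry, extractor,
one-class losses, centering, removal, argmax — can recover well-
separated beat classes from its own supervision.  What it does not
show: performance on real recordings, where morphology variation is
patient-specific and not log-normal, noise is structured, annotation
jitter exists, and class priors are heavily skewed.  Splitting is by
beat, not by patient, which is known to flatter results on real data;
record/patient-level splitting is a known limitation.

## Numerical choices and degenerate inputs

* Everything is float64; the autodiff engine is a minimal reverse-mode
  graph over numpy with gradient accumulation.
* `denoise_wavelet` raises on signals shorter than 2^levels rather than
  silently reducing the depth; the all-zero signal passes through
  unchanged (the threshold is zero and is then skipped).
* `normalize_slice` raises on zero-norm slices.
* Sigmoid/softplus are clipped/computed via `logaddexp` to avoid
  overflow; `−log σ(f)` is softplus(−f).
* H-reg with c ≠ 2 takes a fractional power of the squared gradient
  norm; at exactly zero gradient the derivative of that power is
  unbounded for c < 2, which is why c = 2 is the default.
* Ties in the argmax go to the lowest class index, deterministically.
* WFDB support is a minimal self-contained subset (single-segment,
  format 16, MIT-format beat annotations with SKIP escapes); amplitudes
  quantize to 1/gain mV on write.

## Known limitations

* Beat-level splitting (see above); no inter-patient protocol.
* One-class scorers discriminate only as well as the frozen features
  separate the classes; heavily overlapping classes in feature space
  are irreducible for any density-style scorer.
* The anchor/removal machinery calibrates raw scores across scorers
  only approximately; no probabilistic calibration is attempted.
* The generator does not model respiration, heart-rate variability,
  paced or fusion beats, or multi-lead structure.
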