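# Methods

## Model

The pipeline has three stages: a low-rank dimension-attention block, an
autoencoder that applies it at every encoder layer, and a 1D ResNet-18
classifier on the latent code.

**Low-rank attention.** For `X ∈ R^{n×d}` (samples as rows), the Gram
matrix `G = XᵀX` is factored `G = U diag(S) Vrᵀ`; the attention scores are
the matrix product `P = U·Vr` of the left singular-vector matrix with the
right singular-vector matrix, double-normalized (column softmax over the
row index, then row-sum normalization). Reading the product as `U·Vrᵀ`
would collapse to the identity for the symmetric PSD Gram matrix, making
the attention input-independent; that variant exists behind
`lra_weights(X, product="uvt")` for comparison only. Singular vectors are
sign-ambiguous, so each matched (U, Vr) column pair is flipped to make the
largest-magnitude entry of the U column positive (ties broken at the lowest
row index); this preserves the factorization and makes the product
reproducible across LAPACK backends for non-degenerate spectra. For
repeated singular values (e.g. a rank-deficient Gram matrix when n < d) the
factorization is unique only up to rotations of the degenerate subspace:
determinism is promised for a fixed backend, cross-backend agreement is
not, and the oracle-equivalence tests therefore draw full-rank inputs.

**Gradient isolation.** Attention matrices affect forward values only; the
backward pass treats each `A` as a constant (the gradient of `h·A` with
respect to `h` is `g·Aᵀ`, and nothing propagates into the SVD). With
hand-written gradients this is the natural implementation; the tests verify
it by comparing analytic gradients against finite differences of a
frozen-`A` surrogate (relative tolerance 1e-4) and against finite
differences of the full path, which must disagree.

**Signal flow through the attention — an important property.** Every entry
of `U·Vr` lies in [−1, 1] (columns are unit vectors), so after double
normalization `A` lies within a factor e² of the uniform matrix `1/d`.
Consequently `X·A` preserves each row's **sum** exactly (rows of `A` sum
to 1) while attenuating all other between-sample structure by roughly two
orders of magnitude per layer at d = 250. Inputs whose rows are
individually standardized (row sums ≡ 0) therefore collapse to
near-identical latents. The pipeline standardizes per *record* — one
mean/σ for the whole signal (`Z = (x − μ)/σ`, population σ by default,
sample σ switchable) — which leaves each beat's offset and area intact; the
synthetic generator mirrors this by standardizing the stacked collection
with one global mean/std rather than per beat (`normalization="per_beat"`
restores the destructive variant for study). Under record-style
standardization the class signal rides dominantly on the preserved row-sum
channel, and held-out accuracy on the synthetic classes reaches the
documented floor.

**Autoencoder.** Encoder widths d→128→96→64, decoder 64→128→d, tanh
throughout; widths are configurable, chosen as a monotone compression whose
64-length latent the classifier stem can consume. Training is full-batch
Adam (lr 1e-3, 200 epochs by default; mini-batches configurable) on
reconstruction MSE. Because the final tanh bounds outputs in (−1, 1) while
record-standardized beats exceed that range, the training matrix is
affinely mapped onto [−0.95, 0.95] (one map per dataset, stored in the
checkpoint and applied consistently at encode time); `final_activation:
"linear"` removes the need for the map. The encoder applies a fresh
attention matrix to its current input at every layer and every forward
pass — nothing is cached across epochs.

**Classifier.** The latent is a 1-channel sequence. Stem: Conv(1→3, k3,
s3, p0), Conv(3→64, k3, s3, p0), batch norm, ReLU — for in_length 64 the
lengths are 64→21→7. Four stages of two basic blocks with channels
64/128/256/512; the inner path is conv→BN→ReLU→conv→BN→ReLU (kernel 3,
stride 1, padding 1) and the block output is `F(x) + shortcut(x)`. Stage
entries 2–4 downsample with stride 2 and a 1×1 projection shortcut; a
`no_downsample` switch keeps every block at stride 1 for the literal
constant-length reading. Batch-norm momentum 0.1, eps 1e-5. Global average
pooling then a 4-class fully connected layer; ReLU is `max(x, 0)` with the
boundary assigned to the zero branch. Default parameter count: 3,850,896
(frozen as a regression constant).

**Batch-norm calibration.** The exponential running statistics collected
while the weights are still moving lag the finished network, which at this
data scale is enough to wreck eval-mode predictions even when train-mode
accuracy is perfect. After the last training step the running estimates are
replaced by the exact population statistics of the training set under the
final weights (one train-mode pass with momentum 1 — "precise BN"). This
is applied automatically at the end of `train_epochs` and of joint
training.

**Training strategy.** Default is staged: pretrain the autoencoder, freeze
it, train the classifier on the latents with Adam (lr 1e-3, batch 64,
cross-entropy on logits; an `mse_one_hot` loss mode — squared error between
softmax probabilities and one-hot targets — is available to match a
mean-squared-error reading of the classification loss). `joint_training`
backpropagates the classifier loss through the latents into the encoder
(attention still constant). Prediction is argmax with ties resolved to the
lowest class index. Train/test splitting is stratified per class and
seeded; the default fraction 5/7 on 280 beats/class yields exactly 200
train / 80 test per class.

## Metrics

One-vs-rest TP/FP/TN/FN per class from a rows=true/columns=predicted
confusion matrix; P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R),
Acc = trace/total. Zero-denominator cells return 0 with a `degenerate`
flag rather than NaN so reports stay comparable.

## Synthetic data

Each beat class is a sum of Gaussian bumps (amplitude mV, center s relative
to the R peak, width s) with additive white Gaussian noise (sd 0.04 mV by
default); presets live in `presets.yaml`. N carries a P wave and a narrow
R; L and R are wide-notched and rsR′ double-peaked respectively; V has no P
wave and a ≥1.5× wider QRS than N (asserted by a width-scan test). Rhythm
strips (30 s at 300 Hz) concatenate beats at jittered RR intervals: the
normal preset uses Gaussian jitter (sd 0.02 s about 0.8 s), the
AF-like preset uniform RR in [0.4, 1.2] s (coefficient of variation ≥3× the
normal preset's) with zero P amplitude, and the noisy preset buries the
signal below 0 dB SNR. The generator stores its emitted RR list, R indices
and clean component so these are measured post-conditions, not intentions.

What this does **not** emulate: baseline wander, powerline interference,
electrode artefacts, beat-to-beat morphology drift, heart-rate-dependent
interval scaling, multi-lead projection, or any physiologically validated
waveform model. Passing tests show the pipeline separates classes whose
morphology differences exceed the noise floor under record-style
standardization — they do not certify performance on clinical recordings,
where class overlap, label noise and artefacts are far harsher.

## Numerical choices

- Softmaxes subtract the per-column (or per-row) maximum before
  exponentiation; value-identical, overflow-safe.
- Population (ddof=0) standard deviation in the Z-score; constant signals
  return all zeros with a warning.
- Coordinates are 0-based with half-open windows `[r−pre, r+post)`
  everywhere; the default beat window is pre=100/post=150 samples
  (≈0.69 s at 360 Hz, d=250), with the R peak at sample `round(0.4·d)`.
- Only the first lead of a multi-lead record is segmented by default.
- The epoch loss recorded in full-batch training is the loss evaluated at
  the start of that epoch's step; with mini-batches it is recomputed on
  the full data after the epoch.
- "Non-increasing loss" in the overfit test tolerates rises below 1% of
  the current loss: converged Adam oscillates in a ~0.6% band around the
  floor.
- Checkpoints are `.npz` archives (key → float64 array, config embedded as
  JSON); round-trips are bit-exact.

## Problem sizes

The test suite and the acceptance script run everything from the seeded
generator at desk scale: the end-to-end run uses 280 beats/class
(200 train / 80 test), 200 autoencoder epochs and 30 classifier epochs
(~2 minutes on one CPU); the overfit fixture is 32 beats × 250 samples.
These sizes are the package's reference conditions; larger runs only
require changing `RunConfig`.

## Known limitations

- The attention block's near-uniformity (entries within e² of 1/d) means
  most fine-grained morphology information is carried at ~1% relative
  scale through each layer; classes distinguished *only* by zero-mean,
  zero-sum shape differences are hard for this architecture by
  construction.
- Class-count balancing/record selection for real MIT-BIH replication is
  not prescribed; `segment_beats` takes explicit record lists and a
  seeded `max_per_class` subsampling is left to the caller.
- The WFDB reader covers headers, format 212/16 signals and standard MIT
  annotation codes (including SKIP/AUX words) — not the full zoo of WFDB
  formats.
- No resampling between sampling rates, no QRS detection (annotations are
  taken as given), no denoising.
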