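# Methods

## The model

SqueezeViT is a hybrid CNN/transformer classifier for 224×224
single-channel radiographs that aims at a very small parameter budget
(0.54×10⁶ trainable scalars) while retaining a global-attention stage.
It composes two kinds of blocks:

**Fire modules** (local representation learning). An input map with
C_in channels is squeezed by a 1×1 conv to C_s = max(1, ⌊C_in/2⌋)
channels, re-expanded by parallel 1×1 and 3×3 convs that each produce
C_out/2 channels, and the two excitation outputs are concatenated:

    X′    = ReLU(W_s * X + b_s)
    e_1×1 = ReLU(W_1×1 * X′ + b_1×1)
    e_3×3 = ReLU(W_3×3 * X′ + b_3×3)
    F_out = Concat(e_1×1, e_3×3)

The 3×3 branch uses padding 1 so both branches share spatial dims; a
Fire module therefore never changes H or W. Parameter count per module
is C_in·C_s + C_s·(C_out/2) + 9·C_s·(C_out/2) + biases — strictly less
than a plain 3×3 conv C_in→C_out once C_in ≥ 4. A *Fire Block* stacks N
modules along a channel plan and ends with a 3×3/stride-2/padding-1 max
pool.

**Translution Block** (global context, shape-preserving). From a C=128
map: Fire 128→256, Fire 256→64; the 64-channel map is rearranged into
N = HW/(hw) patches of h×w = 4×4 pixels, giving P = 16 token sequences
of N = 49 tokens (dimension 64) whose order preserves local pixel
position, so no positional embeddings are used. A depth-2 pre-norm
transformer encoder (4 heads, d_k = d_v = 16 per head, FFN width 128,
scaled dot-product attention softmax(QKᵀ/√d_k)·V) mixes tokens across
patches; tokens are folded back, projected by a 1×1 conv to 128
channels, concatenated with the block input (C_output = 2C = 256), and
reduced by a final Fire 256→128.

**Assembly.** Stem 3×3 conv (stride 2, pad 1, 3 output channels) + 3×3
max pool → Stage 1 Fire Block (N = 4, plan 3→32→64→64→128) → Stage 2
Translution Block → Stage 3 Fire 128→256 + pool + 1×1 conv (width 198)
+ global average pooling + fully connected layer to L logits (L = 14,
or 1 in binary normal/abnormal mode). Spatial ledger:
224 → 112 → 56 → 28 → 28 → 14 → 1. The 28-pixel Stage-2 side is an
exact multiple of the 4-pixel patch side; for other input sizes the
tokenizer zero-pads bottom/right and crops after folding.

## Design choices where the design was open

* **Attention scaling** is 1/√d_k (the standard form; it is also the
  form motivated by the vanishing-softmax-gradient argument).
* **Encoder size** (depth 2, 4 heads, 16-dim heads, FFN 128) and the
  **head width 198** were fixed jointly so that the total parameter
  count lands on the 0.54×10⁶ budget; the count is 539,674 and every
  layer's contribution is checkable via `squeezevit.analyze`. The
  encoder has no final layer norm — the block is purely residual, so
  zeroing the attention output projection and second FFN matrix makes
  the encoder exactly the identity, a property the tests exploit.
* **Initialisation.** Kaiming fan-in normals for conv and linear
  weights, zero biases for un-gated layers, and 0.01 for ReLU-gated
  conv biases. Narrow ReLU convs fed by non-negative activations (the
  squeeze bottleneck when C_s ≤ 2, and the 3-channel stem) additionally
  orient each filter to a non-negative coefficient sum — a
  distribution-preserving sign flip of the symmetric He law. Without
  it, the 1-channel squeeze of the first Fire module (plan 3→32) is a
  dead ReLU for roughly half of the seeds and the whole network
  collapses to a constant. The final classifier is zero-initialised so
  training starts from the maximum-entropy predictor rather than from
  randomly saturated logits, and by default the training loop sets the
  classifier bias to the training-set label log-odds (the standard
  head init for imbalanced sigmoid losses) so that the first gradient
  steps carry class contrast instead of re-learning prevalence. All
  randomness flows from a single seed in the network config.
* **Ablations.** `no_translution` replaces Stage 2 by an identity
  pass-through; `fire_nK` (K ∈ {1,4,8,16}) rebuilds Stage 1 with K
  modules over a geometric channel interpolation 3→128 rounded to even
  widths (the published study states no plans for non-default K, and
  its "without Fire Block (N = k)" wording is ambiguous between removal
  and resizing; both a count variant and a disable flag are exposed).
* **MAC convention.** 1 MAC = one multiply + one accumulate; convs cost
  H′W′·C_out·k²·C_in, linears cost tokens·d_in·d_out, attention adds
  P·heads·N²·d_k (scores) and P·heads·N²·d_v (weighted values) per
  layer. Bias adds, ReLU, pooling, softmax and normalisation are
  excluded. The default model costs ≈0.49×10⁹ MACs at 224×224; reports
  show the raw count under both ×10⁹ and ×10¹⁰ scalings because
  published figures for this architecture appear under both.
* **Dropout** is exposed in the attention spec but defaults to 0.

## Training and evaluation

Sigmoid binary cross-entropy (computed in the stable logit form
softplus(z) − y·z), Adam (lr 1e-4, β = 0.9/0.999), batch 64, up to 100
epochs, from scratch, 80/20 image-level random split. The model emits
logits; the sigmoid lives in the loss and at inference.

AUROC is the midrank Mann–Whitney statistic, P(s⁺ > s⁻) + ½P(tie),
computed per class; the average is over classes with both labels
present (single-class columns are skipped with a warning). F1 is
macro-averaged at threshold 0.5 with the zero-division policy F1 = 0
for classes with no predicted and no true positives. Confidence
intervals are nonparametric case-resampling percentile bootstrap
(B = 2000 by default); resamples that lose one class entirely are
redrawn up to 10 times, then dropped with a count. A coverage
simulation (binormal scores with true AUROC 0.8, n = 500, 200
Monte-Carlo repetitions) is part of the test suite.

The binary task retrains a 1-logit head on labels collapsed by the
"No Finding" sentinel (0 iff the record is exactly normal); a
max-over-classes abnormality score of a multi-label model is exposed as
a separately named utility only.

## The synthetic data generator

The generator emulates the *structure* of multi-label chest-radiograph
data — 224×224 single-channel images, 14 binary findings with
configurable prevalence and co-occurrence — without any real data. Each
class owns a fixed template (Gaussian blob, ring, bars, square, cross,
diagonal stripe) at a distinct cell of a 4×4 placement grid, deposited
additively (amplitude 0.5) whenever its label is 1, over a smooth
0.2-base background with additive Gaussian noise (σ = 0.1 by default)
and 8-bit quantisation. Labels are per-class Bernoulli draws (default
prevalence 0.3, uniform) coupled, if requested, through a one-factor
Gaussian copula. Everything is a deterministic function of the seed,
and PNG/CSV output reproduces the in-memory arrays bit-for-bit.

What it does *not* emulate: anatomy and its covariance with pathology,
label noise, patient-level correlation between images, scanner/domain
shift, and realistic class imbalance (unless prevalences are set). A
matched-filter ideal observer (zero-mean template correlation) is
included and used to validate separability of any generated fixture
before a network is trained on it; passing the learning tests therefore
shows that the pipeline can recover planted, linearly detectable
structure — not that it reaches any particular performance on real
radiographs.

## Problem sizes used in the tests

The test suite exercises the published recipe end to end at desk scale:
200 synthetic images, 15 epochs, batch 64, lr 1e-4 on one CPU. The
matched filter validates fixture separability first (per-class AUROC
1.0); the training run is then checked for a monotone loss trend and
for the ranking it recovers. Complexity claims are recomputed
analytically in milliseconds. The bootstrap coverage simulation uses
n = 500 and 200 repetitions. Low-resolution variants (side 16–64) are
used wherever the image side is irrelevant to the property under test.

A caveat the experiments make explicit: 15 epochs over 200 images at
batch 64 is only 60 Adam steps, and at learning rate 1e-4 a
first-order method cannot fully disentangle the 14 overlapping class
signals in that budget — mean train AUROC plateaus near 0.73 (a fully
converged linear probe on the same frozen features reaches 0.9998, and
the plateau is insensitive to batch size, so neither capacity nor the
fixture is the bottleneck; the recipe's step budget is). Full
separation under this recipe needs orders of magnitude more steps, as
in the published 10⁵-image training runs.

## Known limitations

* Pure-numpy execution: training at the full published scale (10⁵
  images × 100 epochs) is out of reach; the package targets method
  correctness and the complexity claims, not dataset-level AUROCs.
* The published MAC figure is ambiguous across sources (0.37 under ×10⁹
  and ×10¹⁰ scalings); this package reports its own exact count both
  ways and pins no claim to either.
* `no_grad` inference is single-threaded and CPU-bound; batch size
  trades memory for BLAS efficiency.
* Patient-level splitting is exposed but image-level is the default
  (the published split is described only as random).
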