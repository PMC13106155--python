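# Methods

## The model

`swinatt` implements a three-class staging classifier for brain MRI
slices (NonDemented / MildDemented / ModerateDemented) built from two
pieces:

1. **Bidirectional spatial attention (ATT)** — a lightweight,
   backbone-agnostic recalibration layer.  For an input feature map
   `x ∈ R^{n×c×h×w}` it computes a per-row descriptor
   `x_h(i) = (1/w) Σ_k x(i,·,k)` and a per-column descriptor
   `x_w(j) = (1/h) Σ_r x(r,·,j)` by adaptive average pooling, stacks
   them along the pooled axis into an `(n, c, h+w, 1)` tensor, and
   passes the stack through a shared bottleneck: a bias-free 1×1
   convolution down to `mip = max(8, ⌊c / reduction⌋)` channels, batch
   normalization (momentum 0.1, eps 1e-5), and the hard-swish
   nonlinearity `x · ReLU6(x+3)/6`.  The result is split back into its
   height and width halves; each half goes through its own 1×1
   convolution (with bias) and a sigmoid, producing row gates
   `x_h'' ∈ (0,1)^{n×c×h×1}` and column gates `x_w'' ∈ (0,1)^{n×c×1×w}`.
   The output is the broadcast product
   `y(i,j) = x(i,j) · x_h''(i) · x_w''(j)`.
   Because both gates are strictly below 1, the layer damps but never
   amplifies; rows/columns crossing salient anatomy keep most of their
   signal while others are attenuated.

2. **A hierarchical shifted-window transformer backbone.**  4×4 patches
   are linearly embedded (224×224 input → a 56×56 grid of 96-channel
   tokens, i.e. 3136 tokens); four stages of pre-norm residual blocks
   apply multi-head self-attention inside non-overlapping 7×7 token
   windows with learned relative-position bias, alternating blocks
   cyclically shifting the grid by half a window (with masking of
   cross-boundary attention); 2×2 patch merging between stages halves
   the grid and doubles the channels; a final layer norm, global token
   average and linear head produce the logits.  The variant presets
   (tiny/small/base/large) follow the standard embed-dim/depth/head
   tables and reproduce the published parameter counts of
   28/50/88/197 M with a 1000-class head — `count_parameters` computes
   these in closed form and the test suite verifies the closed form
   against instantiated models.

The ATT layer sits at the *entry* of each stage listed in
`att_stages` (1-indexed), operating on the unflattened `(B, C, h, w)`
grid.  The default is stage 1 only: directly after patch embedding and
before token flattening, where global row/column context is injected
ahead of the purely local window attention.  For stages 2–4 (used by
the placement-ablation harness) the layer is applied after the
preceding patch merging, i.e. on the entry grid of the stage; this is
the package's documented choice where the placement inside deeper
stages was genuinely open.

## Numerical substrate

All computation runs on the package's own reverse-mode automatic
differentiation engine over float64 numpy arrays (`swinatt.nn`):
broadcast-aware elementwise ops, batched matmul, gather/scatter for the
relative-position tables, layer/batch normalization, and SGD with
momentum and coupled weight decay (`d = g + λp; v = μv + d; p ← p − ηv`).
Softmax and log-softmax subtract a detached per-row maximum for
stability.  Linear and attention weights initialize from a clipped
normal (std 0.02, truncated at ±2σ); ATT convolutions use
`N(0, sqrt(2/fan_in))`; biases and normalization offsets start at zero.
Every stochastic component takes an explicit seed and a same-seed rerun
is bit-identical.

## Data pipeline

Images enter as class-labelled folders (PNG/JPEG) with an optional CSV
sidecar `(filename, subject_id, raw_label)`; without a sidecar the
subject id falls back to the filename stem (documented, overridable).
The four raw severity labels collapse to three (VeryMildDemented →
MildDemented).  Splitting is performed over *subjects* at an 8:1:1
ratio — subjects are shuffled by the split seed and assigned by
cumulative ratio, every image following its subject — so no individual
leaks across train/val/test.  An optional stratified mode performs the
subject split within each class and merges the partitions (still
subject-disjoint); the acceptance script uses it so that the small
held-out partitions of the desk problem contain every class, avoiding
the degenerate macro-F1 readings an absent rare class produces.  Preprocessing resizes bilinearly to the
network input size, scales to [0,1] and standardizes per channel with
the ImageNet statistics (mean 0.485/0.456/0.406, std 0.229/0.224/0.225).

Augmentation draws `ops_per_image = 2` operations per image from
{rotation ≤ ±30°, translation ≤ 10% of the side, shear ≤ ±10°,
brightness and contrast factors in [0.8, 1.2], solarize threshold in
[128, 255]} and applies them in sequence; geometric warps are bilinear
with reflective padding.  Only rotation's ±30° bound is externally
prescribed; the other magnitudes are package defaults chosen to keep
anatomy plausible, all overridable in the policy.  Erasing/cutout-style
operations are rejected at construction: on small-lesion images they
can delete the biomarker that defines the label.  Minority-class
balancing assigns each underrepresented class the ceiling of
(target count / class count) augmented variants per source image —
e.g. 52 minority sources against a ~2600-image majority get factor 50,
yielding 2600 variants — and never touches validation or test items.
With very coarse counts no integer factor lands within 10% of parity;
the plan then still uses the ceiling and records the achieved counts.

## Synthetic phantoms

The generator renders each class as an elliptical bright "brain"
(semi-axes 0.42/0.36 of the image side) containing mid-gray tissue, an
outer bright "cortical" band, and a central dark "ventricle" ellipse.
Severity is encoded geometrically: ventricle radius fractions
(0.08, 0.16, 0.26) increase and cortical band fractions
(0.12, 0.08, 0.04) decrease from NonDemented to ModerateDemented —
proxies for the ventricular enlargement and cortical thinning that
carry the real diagnostic signal.  Gaussian intensity noise (σ = 8 gray
levels), pose jitter (rotation ±5°, translation ±2% of the side) and
three images per synthetic subject emulate acquisition variability and
repeat scans.  Defaults: 60 images per class at 224×224 (56×56 for the
desk preset).

What the phantoms do *not* emulate: real anatomical texture,
inter-subject morphology beyond pose, scanner bias fields, the heavy
class imbalance of clinical data (the generator is balanced by
default), and any overlap between adjacent severity grades.  Passing
the desk-scale training check therefore demonstrates that the
implementation learns end-to-end and that the pipeline is leak-free —
not that the model would reach any particular accuracy on clinical MRI.

## Training protocol

`TrainConfig` defaults encode the full-scale protocol: SGD with
momentum 0.95, weight decay 1e-3, initial learning rate 1e-2, batch 64,
300 epochs, cross-entropy loss, and per-epoch cosine decay
`lr(t) = 0.5 · lr0 · (1 + cos(πt/T))` with no warmup (cosine granularity
is per epoch, matching the epoch-level protocol).  Model selection
keeps the best-validation-loss parameters — the package's documented
choice where none was prescribed.  A non-finite loss aborts with a
diagnostic rather than continuing silently.

The **desk preset** is the package's reduced problem for single-CPU
work: embed dim 24, depths (1,1), heads (2,4), window 7, 56×56
phantoms, ATT in stage 1 (~43 k parameters), with lr 5e-3, momentum
0.9, batch 32 and 15–20 epochs.  On the default phantom set (180
images, 60 subjects) this trains in well under a minute and reaches
≥ 90% validation accuracy; a one-feature threshold on central-region
intensity also exceeds 90%, which is what makes the training check
achievable by construction.

`run_repeated` drives n independent runs (fresh split seed and fresh
initialization per run), training a baseline and a variant on the same
split within each run so the per-run metric differences are paired;
`paired_t_test` then computes `t = mean(d) / (sd(d)/√n)` with the
sample (n−1) standard deviation, a two-sided p-value from the t
distribution with n−1 degrees of freedom, and the 95% confidence
interval `mean(d) ± t_{0.975,n−1} · sd(d)/√n`.  Equal pairs (zero
sample sd) raise a degenerate-case error rather than returning an
arbitrary statistic.

## Metrics

Per-class precision/recall/F1 are one-vs-rest quantities from the
confusion matrix; the macro (unweighted) averages are the headline
aggregates and micro averages are emitted alongside, since a single
overall figure can be computed either way.  A metric with a zero
denominator is reported as 0 with an explicit flag naming the class and
cause.  The suite cross-checks every formula against an independent
implementation and calibrates the paired t test (type-I error 5% ±
1.5%, CI coverage 95% ± 2% over 1000 simulations).

## Numerical choices and limitations

- float64 throughout: simplicity and headroom over speed; the desk
  problem is small enough that this costs seconds.
- Batch-norm running variance stores the unbiased estimate; the batch
  statistics used for normalization are biased (population) moments.
- Shifted-window masking uses the additive −100 convention before
  softmax; shift is disabled when the grid fits one window.
- The window size clamps to the grid when the grid is smaller, so the
  relative-position table always matches the effective window.
- No dropout or stochastic depth; regularization comes from weight
  decay (the L2 term of the optimizer update).
- Single-process, CPU-only by design; there is no multi-device path.
- Checkpoints are zip archives (JSON config + npz parameters), so a
  restored model is bit-identical in eval mode.
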