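# swinatt

Three-class Alzheimer's staging of brain MRI slices (NonDemented /
MildDemented / ModerateDemented) with a **bidirectional spatial
attention** layer (ATT) inserted into a hierarchical shifted-window
transformer classifier, plus the full surrounding pipeline: label
merging, leakage-safe patient-level splitting, medically-constrained
augmentation with minority-class balancing, the SGD/cosine training
protocol, macro-averaged evaluation metrics, and paired t-tests over
repeated runs.  A synthetic brain-phantom generator makes the whole
system trainable and testable on one CPU without any external dataset.

It is intended for researchers studying lightweight spatial-attention
mechanisms in medical image classification, and as a fully inspectable
reference implementation: the entire stack — including reverse-mode
automatic differentiation — is plain numpy.

## The ATT layer

For a feature map `x ∈ R^{n×c×h×w}`, adaptive average pooling collapses
the width axis into a per-row descriptor `x_h = Pool_h(x) ∈ R^{n×c×h×1}`
and the height axis into a per-column descriptor
`x_w = Pool_w(x) ∈ R^{n×c×w×1}`.  Stacked along the pooled axis, the
descriptors pass through a shared 1×1 convolution to a bottleneck of
`mip = max(8, ⌊c/r⌋)` channels, batch normalization and the hard-swish
activation `hswish(x) = x · ReLU6(x+3)/6`; the two halves are then
expanded by independent 1×1 convolutions and sigmoids into row gates
`x_h'' ∈ (0,1)` and column gates `x_w''`, and the output is

    y(i, j) = x(i, j) · x_h''(i) · x_w''(j)

broadcast over the map.  The layer is shape-preserving and
backbone-agnostic; here it sits in stage 1 of the backbone, between
patch embedding (224×224 → a 56×56 grid of 96-channel tokens, 3136
tokens) and token flattening, acting as a global row/column calibrator
ahead of the local 7×7-window attention.  The tiny/small/base/large
backbone presets reproduce the published 28/50/88/197 M parameter
counts.  See `docs/methods.md` for the full model description.

## Worked example

Train the reduced desk-scale preset (embed 24, depths (1,1), ATT in
stage 1, ~43 k parameters) on 56×56 synthetic phantoms — runs in well
under a minute on one CPU:

```python
import swinatt as sa

items = sa.generate_synthetic_dataset(sa.SyntheticSpec(image_size=56, seed=1))
split = sa.patient_level_split(items, seed=1)            # subject-disjoint 8:1:1
model = sa.SwinTransformer(sa.SwinConfig.desk(), seed=1)
config = sa.desk_train_config(seed=1, epochs=15)
model, log = sa.fit(model, split, config)

report = sa.evaluate_model(model, split.test, config)
print(f"test accuracy : {report.accuracy:.3f}")
print(f"macro F1      : {report.macro_f1:.3f}")
print("confusion     :", report.confusion.counts.tolist())
```

Output:

```
test accuracy : 1.000
macro F1      : 1.000
confusion     : [[9, 0, 0], [0, 6, 0], [0, 0, 3]]
```

The phantoms encode severity geometrically (the central dark
"ventricle" grows, the bright "cortical" band thins), so the
held-out-subject test set is fully separable for the trained model; the
confusion matrix rows are the true classes in the order NonDemented,
MildDemented, ModerateDemented.

The same flow is available from the shell:

```
swinatt synth --out data/ --n-per-class 60 --image-size 56 --seed 1
swinatt train --data data/ --out run/ --seed 1
swinatt evaluate --checkpoint run/model.ckpt --data data/
swinatt ablate --placements "1 1,2" --out ablation.csv
swinatt compare --runs-a baseline.csv --runs-b variant.csv
```

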