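# sift2d

Quality scoring and score-gated curation of cryo-EM 2D class averages.

Single-particle cryo-EM pipelines produce dozens of 2D class averages per
classification round, and deciding which classes carry real particles — and
which carry noise, junk or misaligned picks — is still mostly done by eye.
`sift2d` automates that decision for pipeline builders and facility
operators: it scores every class average with a residual convolutional
neural network fused with six physical metadata features, and drives an
iterative, score-gated particle selection workflow that pools good
particles, re-classifies uncertain ones, and discards the rest.

## The model

Each 2D class average is brought to a canonical 210×210 frame (zero-padding
below 210 px, Fourier cropping above; minimum input 31×31) and standardized
to zero mean, unit variance. A residual CNN — 3×3 stem, stages entered
through *pairs of 2×2 stride-2 convolutions* (learned downsampling in place
of pooling), residual blocks with batch normalization, and adaptive average
pooling to a fixed 6×6 grid — maps the image to a feature vector that is
concatenated with six standardized scalar features:

| feature | unit | source |
|---|---|---|
| pixel size | Å/px | image header |
| FRC resolution estimate | Å | classification metadata |
| relative class distribution | fraction | classification metadata |
| deviation from mean mass | kDa | mass estimator |
| deviation from median mass | kDa | mass estimator |
| deviation from mode mass | kDa | mass estimator |

A two-layer regression head emits one continuous quality score on an
**open-ended 1.0 (best) … 5.0 (worst)** scale — trained with MSE loss (Adam,
lr 1e-4, weight decay 1e-4, batch 32), never clamped, so classes worse than
the worst training class score above 5. Scores convert to a [0, 1]
higher-is-better bin scale via `bin = (5 − score)/4`, clamped.

The **mass estimator** segments the particle as all pixels more than
3 standard deviations above the image mean, subtracts the background mean,
sums the particle intensities × pixel size², and converts to kDa with a
through-origin linear calibration fitted on particles of known mass
(slope = Σxy/Σx²).

The **selection workflow** repeats classify → score → disposition:
classes scoring ≤ 2.5 send a seeded random 70% of their particles to the
accepted pool (30% stay in flight to fight the attractor effect); classes
scoring ≥ 4.5 are discarded; the band in between stays in flight. Rounds
follow the extraction box side (5 below 200 px, 3 for 200–300 px, 2 above
300 px). Survivors join the pool, which is classified once more and split
into nested batches at score thresholds 2.5 / 3.5 / 4.5. The classification
engine is a pluggable backend; particle conservation and batch nesting are
asserted on every run.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from sift2d import (SyntheticSpec, generate_stack, TrainingConfig,
                    split_dataset, train, evaluate)
from sift2d.model import feature_matrix

# 1. generate a graded synthetic dataset (200 classes, 64 px, 1.5 A/px)
stack, records = generate_stack(SyntheticSpec(n_classes=200, seed=42))
dataset = list(zip(list(stack.images), records))

# 2. split and train a desk-scale scorer
train_set, val_set = split_dataset(dataset, fraction=0.2, seed=42)
config = TrainingConfig(learning_rate=1e-3, epochs=20, seed=42)
scorer, trace = train(train_set, config, net_config="desk",
                      canonicalize_inputs=False)
print(f"train MSE: epoch 1 {trace[0]:.3f} -> epoch 20 {trace[-1]:.3f}")

# 3. evaluate on the held-out classes
result = evaluate(scorer, val_set)
pred = scorer.predict(([im for im, _ in val_set],
                       feature_matrix([r for _, r in val_set])))
rho = spearmanr(pred, [r.label for _, r in val_set]).statistic
print(f"held-out MSE {result.mse:.3f} (1-5 scale), "
      f"{result.binned_mse:.4f} (0-1 bins), Spearman vs grade {rho:.3f}")
```

Output:

```
train MSE: epoch 1 1.705 -> epoch 20 0.015
held-out MSE 0.323 (1-5 scale), 0.0197 (0-1 bins), Spearman vs grade 0.930
```

The training loss falls two orders of magnitude in 20 epochs, and the
predicted scores rank the held-out classes almost exactly as their
ground-truth quality grades do (Spearman 0.93). The binned MSE is the same
error expressed on the [0, 1] scale, where the affine map divides squared
errors by 16.

The same objects are available from a CLI:

```bash
sift2d simulate --n-classes 50 --out-dir data/        # MRC stack + STAR metadata
sift2d train data/synthetic_classes.mrcs data/synthetic_metadata.star --out-dir model/
sift2d score data/synthetic_classes.mrcs data/synthetic_metadata.star \
       model/scorer.npz --out scores.star             # RELION-displayable STAR
sift2d select --config selection.json --out-dir run/  # nested particle batches
```

Score STAR files use the `_rlnReferenceImage` tag (RELION `NNNNNN@stack`
convention, 1-based) plus the package-defined `_sift2dScore` (continuous,
lower = better) and `_sift2dBinScore` ([0, 1], higher = better) columns.

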