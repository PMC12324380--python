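# Methods

## Scope and shape of the package

`sift2d` scores 2D class averages and gates particle selection on those
scores. The scorer is a scikit-learn-style estimator
(`ClassAverageScorer.fit/predict`, with `net_`, `manifest_`, `loss_trace_`
fitted attributes) so it composes with sklearn tooling; `sift2d.training`
exposes the same recipe as plain functions. The CNN, its backward passes and
the Adam optimizer are implemented directly on numpy: the network is the
package's core contribution and a desk-scale CPU implementation keeps every
result reproducible bit-for-bit from a seed, with no framework dependency.

## Mass estimation

A normalized class average's integrated particle signal above background is
approximately proportional to projected molecular mass. The estimator:

1. **Segmentation.** Particle = pixels strictly above
   `mean(image) + 3·sd(image)`, both moments over the whole image (no
   annulus — the simplest reading, and robust because class-average
   backgrounds are flat). A constant image has sd 0 and yields an empty
   particle mask; downstream, an empty mask gives summed intensity 0.
2. **Background subtraction.** The background mean is subtracted from each
   particle pixel before summing, i.e.
   `Σ_particle(p − mean(bg)) · pixel_size²`. This equals
   `(mean_particle − mean_bg)·n_particle·pixel_size²` and makes the result
   exactly invariant to additive intensity offsets and exactly linear in
   multiplicative gain and pixel area (both property-tested).
3. **Calibration.** `mass = slope · intensity` through the origin (zero
   signal ⇒ zero mass), slope = Σxy/Σx² in closed form; R² is reported
   against that one-parameter model. At least 2 strictly positive points are
   required.
4. **Deviation features.** Per classification job, each class's deviation
   from the mean, median and *mode* of all class masses. The mode of a
   continuous sample is estimated with the half-sample mode (recursive
   shortest-half), parameter-free and robust to the heavy right tail of
   junk-class masses; for n < 3 it falls back to the median.

## Canonical frame and normalization

Class averages are square in every mainstream package; non-square input is
rejected rather than silently reshaped. Below 31 px the image is rejected
(the trunk's receptive geometry and the padding convention assume at least
that side). 31–209 px: centered zero-padding to 210, the extra row/column of
an odd difference placed bottom/right (fixed convention). Above 210 px:
Fourier cropping — the centered DFT window of the target band limit is kept
and amplitudes rescaled by `(out/in)²`, so the mean (DC) and each surviving
mode's amplitude are preserved exactly and output power never exceeds input
power (Parseval-tested). Mean preservation (not total-power preservation)
was chosen because the scorer normalizes intensities afterwards and the DC
level is the only statistic the mass features share.

Intensity normalization (zero mean, unit sd; constant image → zeros) happens
**after** canonicalization, so padded zeros participate in the statistics
deterministically; the convention is recorded in the model manifest so
training and inference always match.

## The scorer network

* Stem: 3×3 conv (pad 1) → batch norm → ReLU.
* Each stage is entered through a **pair of 2×2 stride-2 convolutions**
  (each + BN + ReLU): learned downsampling in place of pooling. A stride-2
  2×2 conv on an odd side is padded by one so the side ceil-halves; a pair
  therefore quarters the side. With the default two stages the trunk ends at
  14×14 for a 210-px input. (Four such stages — 8 halvings — would collapse
  even 210 px to a single pixel and make the 6×6 pooling vacuous, which is
  why two stages is the default; stage count and widths are configurable.)
* Per stage, `blocks_per_stage` identity-skip residual blocks
  (conv3×3–BN–ReLU–conv3×3–BN, add, ReLU).
* Adaptive average pooling to a fixed 6×6 grid (cell (i,j) averages rows
  ⌊iH/6⌋…⌈(i+1)H/6⌉), so any input side ≥ 31 yields the same flattened
  width; inputs smaller than the grid are replicated.
* Head: flattened 6×6 activations ⊕ the 6 standardized features → affine →
  ReLU → affine → one unbounded score. Late fusion keeps the metadata
  pathway linear and auditable.

Defaults: stem 32 channels, stages 64→128, 2 blocks per stage, head hidden
64. The desk configuration (stem 4, stages 8→16, 1 block, hidden 32) is used
for CPU-scale tests and yields ~30 s per 500-image × 30-epoch training run.

Features are z-scored with training-set statistics stored in the manifest
(they span Å, kDa and fractions; unstandardized scales would dominate the
head). A feature with zero variance gets sd 1 so it contributes exactly
zero after centering. Inference refuses to run without manifest statistics.
FRC resolution enters in Å (not spatial frequency), recorded in the
manifest. Weights are He-initialized from the training seed; weights and
manifest serialize together and a SHA-256 checksum is verified on load.

Scores are never clamped. The bin conversion `(5 − s)/4` (then clamped to
[0, 1]) sends 1 → 1 and 5 → 0; the orientation reverses because the
package's scale is lower-is-better while [0, 1] ranker scores are
higher-is-better. The inverse map is provided and the choice is trivially
switchable.

## Training recipe

Adam with the optimizer's native L2 penalty (added to the gradient, not
decoupled) at 1e-4, learning rate 1e-4, batch size 32, 200 epochs, MSE loss
on the 1–5 labels, no learning-rate schedule — these are the package
defaults for full-scale training. Grade letters map A,B,C,D,F → 1…5. Data
order and initialization derive from one seed; training is bit-reproducible
on CPU. The last incomplete mini-batch is kept, except that a trailing
singleton is merged into the previous batch (batch norm needs ≥ 2 samples).
Evaluation reports MSE on the native scale *and* after bin conversion of
both prediction and label, plus a 10×10 decile confusion matrix; when all
scores lie in [1, 5] the binned MSE is exactly MSE/16.

Desk-scale runs (tests, acceptance script) use the reduced-width network,
500 synthetic classes at 64 px fed at native size, 30 epochs and learning
rate 1e-3: a ~500-step run needs a proportionally larger step than the
6,000-step full recipe. Under those conditions the training loss falls
roughly two orders of magnitude and the held-out Spearman correlation
between predicted score and true grade is ~0.9 (both recomputed by
`scripts/acceptance.py`). The degenerate regression check (all labels
identical) converges within 0.1 of the constant in about 100 epochs at desk
scale — the network's input-dependent pathway decays through weight decay
and gradient pressure, which takes longer than fitting the bias.

## Selection workflow

Boundary semantics are encoded once: score ≤ good cutoff (2.5) triggers the
70/30 split; score ≥ accept cutoff (4.5) discards; strictly between keeps
the class in flight. The set-aside count is round-half-up of
`fraction × members`, drawn per class (not globally) from a generator seeded
by `(run seed, round index)` — so a run resumed from a snapshot finishes
identically to an uninterrupted one, and reruns are byte-identical. The
set-aside 70% goes to the accepted pool by default (`pool_setaside=True`);
discarding well-scoring particles would contradict the tool's purpose, but
the flag allows the stricter reading. Rounds: 5 for boxes < 200 px, 3 for
200–300 px, 2 for > 300 px (box side proxies particle size; small particles
benefit from more re-classification). After the last round, surviving
in-flight particles — all of which scored below the accept cutoff in their
final class — join the pool; the pool is classified and scored once more and
split into nested batches at ≤ 2.5 / ≤ 3.5 / ≤ 4.5.

Invariants asserted at every step: pooled/in-flight/rejected are pairwise
disjoint and their union is the initial particle set (conservation); final
batches are nested. The backend is any callable returning a partition of its
input with per-class metadata; the workflow assumes nothing else, verified
against structurally different mocks.

## Synthetic data

The generator emulates the *structure* of an expert-graded corpus, not its
content. Phantoms are mixtures of 3–5 Gaussian blobs near the image center
(width side/12–side/8, amplitude 0.8–1.2 — deliberately narrow ranges so the
grade, not phantom-to-phantom variability, dominates image quality). Grade
g ∈ 1…5 controls a soft radial low-pass (0.9 → 0.2 of Nyquist, 8th-order
rolloff) and additive Gaussian noise on a geometric ladder (sd 0.04, 0.16,
0.64, 2.5, 10 in blob-amplitude units — SNR from ~25 for a sharp grade-1
class to ~0.1 for an unusable grade-5 one). Each class average is the mean
of two independently noised half-images (each at sd·√2), so the metadata's
FRC resolution is estimated exactly as half-set resolutions are in practice:
ring correlation between the halves, smoothed with a 5-ring moving average
(single-pair crossings on 64-px images are otherwise too jittery), first
crossing of 0.143 linearly interpolated, Nyquist (2·pixel size) when the
curve never drops that low. Class distributions are one seeded Dirichlet
draw (sum exactly 1); masses come from the mass estimator applied to the
clean phantom. Regeneration from the same spec is bit-identical.

What the generator does **not** emulate: CTF modulation, beam-induced
motion, picking artifacts, preferred orientation, real particle shapes, or
annotator disagreement. Passing tests therefore demonstrate that the
architecture can learn a monotone quality gradient and that the machinery
(preprocessing, training, scoring, selection bookkeeping) is correct — not
that a desk-trained model transfers to experimental class averages, which
requires a real labeled corpus.

## Numerical choices and degenerate inputs

* MRC written as little-endian mode 2 (float32), ISPG 0, NVERSION 20140;
  modes 0/1/2/6 accepted on read. Pixel size from CELLA/M per axis, x/y must
  agree within 1e-3 relative; a zero cell falls back to 1 Å/px.
* Slice indices are 0-based everywhere except the `NNNNNN@stack` STAR image
  reference (1-based, as display tools expect). Scores print with %.8g
  (round-trip ≥ 6 significant digits).
* Class distributions summing to k ∈ [0.9, 1.1] but ≠ 1 are renormalized
  with a warning; outside that window it is an error.
* Conv biases feeding batch norm have exactly zero gradient (BN subtracts
  the channel mean); the gradient check accounts for this with an absolute
  tolerance floor.
* Batch-norm running statistics use momentum 0.1; inference always uses
  running statistics, making two forward passes bitwise identical.

## Known limitations

* No trained weights ship with the package; the published corpus-scale
  training (32k expert-labeled averages, 200 epochs) is out of desk reach,
  so corpus-level error rates are not reproduced here.
* The numpy training loop is single-process and CPU-bound: fine for
  desk-scale experiments, not for corpus-scale training.
* No real 2D-classification backend is bundled; production use requires an
  adapter from a classification engine to the backend contract
  (`ClassificationResult`).
* Fourier cropping assumes square images and leaves a negligible (≤ 1 ulp
  scale) imaginary residue that is dropped; non-square support is
  deliberately out of scope.
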