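# Methods

This note documents the models, defaults and design choices behind
`pluckseg`, and what the synthetic benchmark can and cannot show.

## Model

Auto-context iterates a per-cell K-class classifier T times. The input
vector at foreground cell i is, in fixed order:

1. **local appearance** (36 values by default): the image is converted to
   CIE 1976 L\*u\*v\* (sRGB primaries, D65 white point) and each channel
   undergoes a recursive 2-D Haar decomposition to 3 levels (symmetric
   boundary padding). At each level the approximation map and the
   *squared* horizontal/vertical/diagonal detail maps are kept — squaring
   makes the detail response a local energy, insensitive to contrast
   polarity; the approximation is left unsquared. Every coefficient map is
   upscaled to the source size by nearest-neighbour (Haar coefficients are
   piecewise constant, so smoother interpolants would invent gradients)
   and subsampled by an integer factor, taking the top-left pixel of each
   block with the grid origin at (0, 0). 3 channels × 4 coefficient kinds
   × 3 levels = 36 planes.
2. **stencil context** (|stencil|·K values): class probabilities of the
   previous iteration's map at each stencil offset. The default stencil is
   10 equally spaced rays × 9 radii (2, 4, 7, 11, 16, 22, 29, 37, 46 grid
   cells, roughly log-spaced) plus the centre — 91 points. Offsets are
   `(round(r·sin θ), round(r·cos θ))`; radii whose rounded offsets collide
   are rejected at construction. Out-of-bounds or background points
   contribute the padding distribution, uniform 1/K — maximal label
   uncertainty outside the object, biasing no class.
3. **integral context** (2K values, IC variants): per-class means over the
   foreground cells of the query's row, then over the whole foreground.
   Means rather than sums: masks differ in size between images and means
   keep the feature scale comparable.
4. **atlas context** (|stencil|·K values, WAAC variants, iterations ≥ 2):
   the stencil applied to the image's adaptive weighted atlas. Iteration 1
   runs as plain AC — before any prediction exists the weighted atlas
   would merely duplicate the prior atlas (a flag restores the duplicated
   behaviour if wanted). Integral features are computed on the probability
   map only, keeping the IC and WAAC feature blocks orthogonal.

Probability maps are initialised from the prior atlas (unweighted mean of
the one-hot training annotations; union-of-foregrounds mask). The weighted
atlas ranks candidate annotations by mean class F1-score against the
current probability map (hard-assigned by arg-max), selects the m_w
largest weights and combines the selected one-hot maps convexly. Classes
absent from both maps are excluded from the F1 mean (no evidence either
way); a class present on exactly one side contributes 0, so hallucinating
a missing organ is penalised. Ties at the selection boundary break by
identifier ascending; arg-max ties break to the lowest class index — both
purely for cross-platform determinism. If every selected weight is 0 the
selected maps are averaged unweighted. At training time the image's own
annotation is excluded from its candidate pool; at test time the full
training pool is used with no exclusion. No spatial registration is
performed: acquisition is hook-aligned, so annotations are averaged in the
image frame (resampled nearest-neighbour if grids differ).

## Classifier

A single-hidden-layer perceptron: 20 logistic units, softmax output,
L2-regularised cross-entropy (default strength 1e-3, exposed). The
contract is the model family, not the optimiser; L-BFGS is used because it
is full-batch and bit-reproducible given a seed, with tolerance 1e-5 on
the loss change and an iteration cap (default 500). Inputs are
standardised to zero mean and unit variance on the training sample —
the vector mixes bounded probabilities with squared wavelet energies
spanning orders of magnitude, and the logistic units saturate without it.
Training locations are a stratified sample, `per_class_samples` per class
(default 1600), drawn without replacement across the pool. All randomness
flows from one root seed via `SeedSequence` hashing with fixed role tags
(sampling, per-iteration classifier, fold splitting, dataset generation),
so every run is reproducible end to end.

## Evaluation

Per-organ Dice 2|X∩Y|/(|X|+|Y|); organs absent from the ground truth are
marked absent and excluded from medians (a predicted-but-absent organ
still shows as false-positive area in the confusion matrix). The headline
"class average" is the mean of the K per-class medians. The quadratic
score 2·r_true − Σ_c r_c² is averaged over foreground cells per image and
summarised by the median over images. All evaluation is restricted to
foreground cells. Cross-validation shuffles images deterministically from
the seed and splits them into folds; a held-out image containing a class
missing from its training pool triggers a warning and is retained.

## Synthetic plucks

The generator emulates the structural regularities the methods exploit,
not anatomy: a vertically elongated silhouette anchored at the top row
(the hook), partitioned top-to-bottom into upper, a lungs band with an
embedded heart ellipse, diaphragm and liver; per-class colours with
Gaussian texture noise, per-image colour jitter and sparse near-white
speculars. The heart ellipse slides sideways with `orientation` ∈ [−1, 1]
so its visible area shrinks to zero at |orientation| = 1, and the visible
diaphragm band thins with |orientation| in the same way: across a
population, visible heart area and visible diaphragm proportion vary
*together* (small diaphragm ⇔ hidden heart ⇔ large lung share), which is
exactly the cue whole-image integral features pick up. The liver is
missing with probability 0.02. Heart and liver colour means are
deliberately close relative to the noise so local appearance cannot
separate them reliably and context features carry real signal.

Defaults: 180×60 grids, noise SD 9 (8-bit scale), colour jitter SD 8,
specular rate 0.004, orientation uniform over [−1, 1].

What the synthetic data does **not** emulate: real organ shape and
boundary geometry, surface contaminants and pathology-driven appearance
change, correlated (non-Gaussian) texture, the focus/hue foreground
segmentation of real images (the true mask is emitted directly), and
perspective effects. Passing benchmarks here show the algorithms are
implemented correctly and that context/atlas adaptation works as designed
on data with the stated structure — they do not predict absolute accuracy
on abattoir imagery.

## The scaled benchmark

Routine testing uses a fixed desk-scale configuration
(`pluckseg.benchmark`): 30 plucks on 60×30 grids, 3-fold
cross-validation, T = 5, 400 samples per class, a 41-point stencil
(10 rays × radii 2, 4, 7, 11 — the default radii reach 46 cells and would
overshoot the grid), MLP iteration cap 120 (the loss plateaus well before
that at this problem size). `m_w` stays at its default 32, which on a
20-map training pool keeps every annotation selected; the occlusion probe
is the exception and uses m_w = 2 (10% of the pool, the study-scale
ratio), because the probe specifically exercises the selection mechanism,
which is inactive whenever m_w ≥ pool size.

Two honest caveats. First, the synthetic task is easier than the real
one: all variants reach ≈0.93–0.95 class-average median Dice against a
0.84 prior-atlas baseline, so the differences *between* variants are
small (order 1e-3 in the medians over ten dataset seeds) and only their
direction, not their magnitude, is asserted. Second, with the 20-map
pools of this benchmark the m_w=32 default disables atlas selection
inside cross-validation; the adaptive-selection behaviour is exercised
separately by the occlusion probe, where the final WAAC atlas's heart
mass on fully occluded plucks falls well below half of its frontal-view
value.

## Degenerate inputs and numerical choices

Probability rows from the classifier are clipped at 0 and renormalised
before re-entering the pipeline (guards 1e-16-scale drift). Per-cell
distribution sums are validated to 1e-6 throughout. Rows without
foreground cells carry the padding distribution in the row-integral plane
but are never legal query locations. A stencil is required to contain the
centre exactly once; a class with no foreground cells anywhere in a
training pool is a hard error naming the class. Wavelet decomposition
requires both image dimensions ≥ 2^levels.
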