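# Methods

This note records the scientific and numerical choices behind `isoscan`, in
the spirit of a model-description appendix: what is computed, under which
assumptions, and what the bundled synthetic data can and cannot establish.

## Problem and model

The classification target is early Parkinson's disease (PD) versus normal
control (NC) from dopamine-transporter SPECT. After spatial registration
(assumed done upstream) and intensity normalization, the diagnostic signal
is the shape and bilateral symmetry of striatal uptake: PD reduces
putaminal binding, usually asymmetrically, while the caudate is relatively
spared.

Rather than classifying raw voxels, the pipeline thresholds the normalized
volume at levels `t ∈ (0, 1)` and represents each threshold by its
isosurface — the boundary of the super-level set `{v : I(v) ≥ t}` of the
trilinearly interpolated field. Surfaces at increasing levels are nested
and never cross; their spacing encodes the intensity gradient. For CNN
input each level becomes one channel on the original ROI grid, so a set of
`n` levels is an `n`-channel 3D image and `n` is exactly the `#inputs` of
the first convolution's parameter count.

### Channel encodings

The surface-to-channel encoding is a design choice (the surface itself is
not a grid). Three rasterizations are provided:

- `binary` (default): voxel intensity ≥ level → 1. Minimal and faithful to
  the super-level-set definition; ties at exactly the level count as
  inside, which keeps super-level sets closed and the encoding
  deterministic.
- `fractional`: per-voxel occupancy of the super-level set, estimated by
  3×3×3 trilinear supersampling (offsets ±1/3 voxel). Honors the
  interpolated-surface reading: uniform interior/exterior voxels come out
  exactly 1/0, boundary voxels take intermediate values.
- `shell`: 1 only on voxels adjacent to a binary sign change — the voxels
  the extracted mesh passes through.

Meshes themselves use the topology-correct (Lewiner) marching-cubes
variant in voxel coordinates, with no smoothing or decimation, so surface
areas and exports are reproducible. Disconnected components at one level
are kept in a single mesh.

## Architectures and accounting

Two small 3D CNNs are specified declaratively and realized by a numpy
backend (no deep-learning framework is assumed by the package):

- LeNet-style: `conv(5@3³) → pool → conv(5@3³) → pool → flatten(3,080) →
  dense(4,096) → dropout(0.5) → dense(2, softmax)`;
  12,628,790 parameters at one channel.
- AlexNet-style: `conv(10@7³) → pool → conv(8@6³) → pool → conv(7@5³) →
  conv(6@4³) → conv(5@3³) → pool → flatten(480) → dense(2,048) →
  dropout(0.7) → dense(2,048) → dropout(0.7) → dense(2, softmax)`;
  5,216,782 parameters at one channel.

Conventions forced by the printed feature-map arithmetic: all convolutions
are stride-1 and "same"-padded (even kernels split the padding as
`(k-1)//2` before, `k//2` after); 2×2×2 max pooling is ceil-mode (odd
extents round up: 29→15→8→4, 41→21→11→6). Hidden activations are ReLU
(unstated in the source description; standard for these families), the
output is a 2-way softmax. Initialization is He-uniform with zero biases,
fully seeded. Parameter counts are computed twice by independent routes —
symbolically from the layer stack and from the realized array sizes — and
must agree; backpropagation is validated against central finite
differences in the test suite.

## Training recipe

Adam (lr 1e-4), softmax cross-entropy, batch size 16, up to 100 epochs
with early stopping on a stratified 15% held-out accuracy (patience 10) —
all overridable per run. The desk-scale evaluations in the tests override
to lr 1e-3 and ≤ 5 epochs, which the easy phantom contrast makes
sufficient (training loss reaches ~1e-3 by epoch 4); this is a runtime
concession, not a statement about clinical data.

## Evaluation protocol

Nested stratified k-fold CV (default k=10). The inner loop, run only on
the outer-training portion, scores candidate level sets by mean inner-fold
accuracy and drives a greedy search: forward selection starts from the
best single level and adds levels only on strict improvement; backward
selection starts from the full set and removes levels while the score does
not decrease. Ties prefer fewer levels, then higher thresholds (higher
levels enclose less volume, hence lower input complexity). Only the
candidate sets the greedy path visits are ever trained.

Per-fold error is the mean squared residual between the binary PD
indicator and the predicted PD probability; the dispersion of the k fold
errors gives `SD` (sample variance, ddof=1 — the standard convention for a
standard error of the mean) and `SEM = SD / √k`. Accuracy, sensitivity and
specificity use threshold 0.5 with PD as the positive class; ROC/AUC comes
from the full threshold sweep and equals the Mann–Whitney pairwise
statistic (the test suite checks this against exhaustive pair counting).
AUC samples are compared with a two-sided Welch unequal-variance t-test;
when both samples are constant the p-value is 1 for equal means and 0
otherwise.

## Saliency

Saliency is `|∂s_c/∂x|` where `s_c` is the **pre-softmax** class score:
post-softmax gradients vanish as the model saturates, while logit
gradients stay informative and are invariant to the softmax's shared
normalizer (asserted in the tests). Channels are reduced by max of
absolute value (default) or mean. The summary statistic
`region_mass_fraction` — the fraction of total saliency mass inside a
mask — quantifies localization: for a model trained on real structure it
should exceed the mask's volume fraction, while for a model trained on
pure noise it is statistically indistinguishable from it (permutation
check in the tests).

## Synthetic phantoms

Each phantom is built on the `(29, 25, 41)` ROI grid from four geometric
primitives: a spherical "caudate" (radius 3 voxels) and an elongated
ellipsoidal "putamen" (semiaxes 2.5×3×5.5 voxels) per hemisphere, mirrored
about the mid-sagittal plane, at unit uptake over a 0.02 background. PD
multiplies the affected putamen's level by `pd_putamen_factor` f and the
contralateral one by `f + asymmetry·(1−f)`; the caudate is spared. A
Gaussian PSF (σ = 1.2 voxels) emulates SPECT resolution, additive Gaussian
noise (σ = 0.05) the reconstruction noise, and the volume is clipped at 0
and min-max scaled to `[0, 1]`. Cohort generation jitters centers by ±0.5
voxels and contrast levels by ±5%, emulating residual registration error
and uptake variability. Everything is reproducible from a single seed.

Two analytic facts anchor the defaults:

- Min-max scaling maps the affected/contralateral putamen mean-uptake
  ratio to exactly `(f − b)/(1 − b)` (the PSF retention factor cancels),
  so the background `b` must stay small for `f` to keep its meaning on the
  final volume; `b = 0.02` keeps the realized ratio within 2% of `f`.
- At `f = 1, asymmetry = 0` the classes are identically distributed, so
  any classifier's AUC tends to 0.5; the tests check that AUC rises
  monotonically as the deficit deepens.

What the phantom does **not** emulate: anatomy (the striatum is not two
ellipsoids), the SPECT projection/reconstruction chain (attenuation,
scatter, Poisson counting), registration failures, scanner differences,
and age/sex covariates. A green phantom test therefore establishes that
the pipeline's machinery is correct and that it can exploit the
symmetric-vs-asymmetric uptake contrast — not that clinical-scale accuracy
would be reproduced on patient data, which is access-controlled and out of
scope here.

## Numerical and degenerate-input choices

- ROI boxes are 0-based, half-open `[start, start+size)`; the default box
  is centered (registration puts the striatum near the template center)
  and fully overridable.
- Integral normalization uses the whole-image mean by default; an optional
  exclusion mask supports the variant that leaves out the striatum.
  Zero/negative means and constant volumes raise degenerate-input errors
  rather than returning NaNs.
- Iso levels must lie strictly in (0, 1); a level no voxel pair straddles
  yields an empty mesh (not an error). Duplicate levels in a channel stack
  are rejected; stacks store levels sorted ascending, so binary channels
  are nested by construction.
- Sphere-area validation smooths the binary phantom with a fixed σ = 1
  voxel (anti-aliasing): the curvature-induced bias of the 0.5 level set
  scales as σ²/r, so the relative area error shrinks as resolution grows —
  a smoothing width proportional to the radius would instead freeze the
  error at a constant.
- All stochastic stages (fold shuffling, weight init, dropout, batch
  order, phantom noise) derive from one master seed; derived seeds stay
  below 2³¹.

## Known limitations

- The numpy backend targets small 3D grids; it is single-threaded
  BLAS-bound and has no GPU path. Training the AlexNet variant at clinical
  cohort sizes is possible but slow.
- Early stopping monitors a held-out split of the training portion only;
  the inner CV loop selects level sets, not training hyperparameters.
- `fractional` rasterization supersamples at 27 fixed offsets; it is an
  occupancy estimate, not an exact polyhedral volume fraction.
- Isoline extraction operates on grid-aligned slices only.
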