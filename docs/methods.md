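# Methods

## Distance maps

`compute_dptv` is the Euclidean distance transform of the PTV-mask
complement with `sampling=spacing`, i.e. the minimum distance between voxel
*centers* in physical mm, computed in full 3D. This is identical to the
distance to the PTV *surface* up to half-voxel discretization and treats
anisotropic grids (clinical 3 mm slices vs ~1 mm in-plane) correctly;
distances in voxel counts would not. Two conventions are deliberate and
kept:

* PTV voxels **and** voxels outside the body are both coded 0. The
  encoding is ambiguous on its own, but the structure-map channel
  disambiguates, so the predictor always sees both together.
* The map is unsigned; no signed boundary distances, no per-OAR distances.

The test suite pins the transform to an exhaustive nearest-PTV-voxel
search on randomized anisotropic grids (max deviation ≤ 1e-6 mm) plus a
Lipschitz property (values cannot change faster than physical separation)
and exact scale covariance in the spacing.

## Structure maps

One integer-labelled volume per case. Organs at risk get small consecutive
codes (3, 4, …), targets get widely spaced codes (100, 200), the body code
is 1 and out-of-field voxels get 2; a voxel inside both an organ and a
target is coded as the **sum** of the two labels. With ≤ 97 organs the sums
are collision-free by construction, and the label table validates this.
Two precedence rules close the gaps a sum rule cannot: nested targets keep
the innermost (higher-prescription) code, and overlapping organs keep the
first-listed code (base organs are listed before their PRV expansions).
In-field voxels outside the body keep 0. Non-overlapping ROIs are exactly
recoverable from the map given the table (tested).

## Input normalization

CT is windowed linearly from [−1000, 1000] HU to [0, 1]. Structure codes
are divided by the largest valid code. The distance channel is divided by
a 150 mm cap and clipped to [0, 1] — distances beyond that carry no
planning information and bounded inputs keep training stable. All three
constants are parameters of `assemble_inputs` / `DosePredictor`.

## The predictor

A slice-wise (2D, axial) fully-convolutional regressor:

* stem: 7×7 convolution, 64 filters, stride 2; BN; ReLU; 3×3 max-pool
  stride 2;
* four stages of residual bottleneck blocks (1×1 → 3×3 → 1×1 with identity
  or projection skip), default depths (3, 4, 23, 5);
* output stride held at 1/8: stride 2 only in the stem, the pool and the
  second stage; the last two stages run at stride 1 with dilation 2 and 4
  (the standard dense-prediction adaptation of a classification backbone);
* decoder: three ×2 fractionally-strided deconvolutions back to full
  resolution. Each is followed by a 3×3 refinement convolution — bare
  k2s2 deconvolutions leave blocking artifacts that dominate the voxel
  error budget. Decoder widths are floored (32/24/16 channels) rather than
  scaled by the width multiplier: the decoder is a negligible fraction of
  the compute but throttling it starves the upsampled dose pattern.

A `width_multiplier` scales all channel widths so desk-scale runs keep the
topology. Everything (im2col convolution, BN, pooling, deconvolution,
Adam) is implemented in NumPy with manual backpropagation (`kbdose.nn`);
each layer's gradient is checked against central finite differences in
float64.

Training: slice-wise regression of dose normalized by the boost
prescription (69.96 Gy), so targets stay near [0, 1]. Loss is MSE by
default (configurable to MAE — MAE directly optimizes the reported metric
and is the better choice when memorization capacity itself is under
test). Optimizer is Adam; the default schedule is cosine decay of the
learning rate, which also settles the batch-norm running statistics used
at inference. Seeds fix initialization and shuffling, so training is
bit-reproducible on a fixed platform. Predictions are de-normalized to Gy
and clipped at 0.

Depth note: the printed stage depths (3, 4, 23, 5) are kept as defaults
even though they do not arithmetically yield a standard 101-layer network
(the classic variant uses 3, 4, 23, 3); the depths, not the layer count,
are what the architecture definition pins down.

## The phantom and its dose engine

Geometry: an elliptical body (with a schematic bone shell; HU tiers −1000
air / ~40 soft tissue / ~700 bone plus Gaussian texture), a PTV ellipsoid
with a strictly interior boost ellipsoid, and 21 OARs (paired lenses,
optic nerves, parotids, mandibles, TMJs, temporal lobes; chiasm,
pituitary, larynx, thyroid, trachea; brain stem and spinal cord with 3 mm
and 5 mm PRV expansions computed by distance transform). The treated field
is the axial slab within `field_margin_mm` (default 6 mm) of the target
extent — a simple stand-in for coplanar-arc field edges; out-of-field is
everything beyond it.

Dose (before noise): boost voxels at 69.96 Gy, remaining PTV at 60.06 Gy,
in-field normal tissue at `60.06 · exp(−DPTV/τ)` with τ = 25 mm, times an
organ-sparing multiplier (serial structures pushed hardest, e.g. cord
0.35; the smallest multiplier wins where organs overlap), out-of-field
scaled by 0.02, zero outside the body. Additive Gaussian noise (default
0.5 Gy in cohort runs) is applied inside the body and clipped at 0.

What this emulates — and does not: the dose is a *deterministic function
of distance and structure labels*, which is exactly what makes the
COM-vs-ANAT contrast a controlled experiment (the distance channel is
sufficient by construction). Real VMAT dose also depends on beam
geometry, modulation limits and optimizer trade-offs, none of which are
modelled; passing the directional comparison here shows the predictor
exploits the distance channel when it is informative, not that the same
margin would appear on clinical data.

Default desk grid is 64×64×16 at (4, 4, 3) mm — anisotropic like clinical
CT so spacing-aware code paths stay exercised — with prescriptions and
fraction count (33) at their clinical values.

## Study design

Cohorts are drawn by jittering the base geometry per case (PTV center
±8 mm in-plane, sizes ±15 %, organ centers ±5 mm), with per-case seeds
derived from a master seed. k-fold splitting is shuffled and seeded;
folds are disjoint, exhaustive, and differ in size by at most one. Both
input modes are trained per fold from independent seeded initializations
and evaluated on the held-out fold only.

Desk-scale experiment defaults (`ExperimentConfig`): 40 cases on a
32×32×8 grid at (8, 8, 6) mm, 2 folds, one bottleneck block per stage at
quarter width, 10 epochs, lr 3e-3, dose noise 0.5 Gy — sized so the full
two-model comparison completes in a few minutes on one CPU while keeping
the study's structure. The full-scale setting (100 cases, 10 folds,
depths 3/4/23/5, 100 epochs) is a plain config change.

## Evaluation

* **ME/MAE** per case and ROI as percent of prescription, aggregated as
  an unweighted mean over cases (per-case mean first, never pooled
  voxels). With two prescription levels the denominator is ambiguous; the
  default policy uses the boost prescription (69.96 Gy) for body, whole
  normal tissue (body minus targets) and OARs, and each target's own
  prescription for target rows. This choice rescales every percentage and
  is configurable (`denominator_policy`).
* **Isodose DSC** thresholds both volumes at ≥ level (the closed bound is
  a convention; nothing pins the inequality direction). Curves run
  1–60 Gy; statistics use 5–55 Gy in 5 Gy steps plus 60 Gy (12 levels).
  When both isodose volumes are empty the DSC is defined as 1.0 and
  flagged — agreement on absence.
* **DVH** is cumulative with 0.1 Gy bins by default; **Dx%** interpolates
  linearly inside the crossing bin (exact to one bin width; tested against
  a sort-based order statistic). Mean dose equals the DVH integral to
  within a bin width (conservation test).
* **Paired comparisons** are two-sided paired t-tests; identical
  difference vectors are flagged degenerate with p = 1 instead of the
  undefined 0/0 statistic.

## Numerical and degenerate-input choices

* Distance transform on an empty PTV, mask shape mismatches, empty
  evaluation masks, k > cohort size, non-positive prescriptions and
  out-of-range sparing multipliers all raise `ValueError` early.
* Network inputs whose height/width are not multiples of 8 are zero-padded
  and the output cropped (logged contract, tested).
* Non-finite training loss aborts with the epoch and batch in the message.
* CSV outputs are written with a fixed float format so reruns are
  byte-identical.

## Known limitations

* The dose engine has no beam/arc physics; field edges are axial planes.
* 2D slice-wise inference ignores inter-slice context (a 3D variant is an
  obvious extension, not implemented).
* The NumPy training loop is single-threaded BLAS-bound; full-scale
  (512×512, depths 3/4/23/5, 100 epochs) training is expressible but not
  practical on one CPU.
* Bit-reproducibility is per-platform (BLAS reduction order may differ
  across builds).
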