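# Methods

## Linear-quadratic dose equivalence

The LQ engine implements the basic Fowler form of the biologically
effective dose, BED = (n·d)(1 + d/(α/β)), with no time-factor or
repopulation term: schemes delivered over one to two weeks are compared on
fraction-size effects alone, and protraction/repair corrections (e.g.
incomplete-repair models using a repair halftime) are out of scope. The
single-fraction equivalent dose is the non-negative root of the quadratic
obtained by setting n = 1, d = SFED:

SFED = (−1 + √(1 + 4·BED/(α/β))) / (2/(α/β)).

The negative root is never returned; SFED(0) = 0, SFED of a single-fraction
scheme is its dose, and at fixed total dose both BED and SFED strictly
decrease as the dose is split into more fractions (the sparing property the
tests verify). α/β is treated as a grid of discrete values — 2 and 3 Gy as
the conventional bracket for late-responding cerebrum, 10 Gy for
early-responding tissue — rather than a continuous uncertainty.

Table comparisons in the tests use the printed precision of the reference
values: BED to the number of decimals printed per cell, SFED to 2 dp.

## Scan geometry and I/O

Volumes are stored (slice, row, col), 0-based, slice 0 most anterior;
anatomical orientation does not affect volumetry. In-plane resolution is
FOV/matrix per axis and the voxel unit volume is the pixel area times slice
thickness; for the default 128×128 / 15×15 mm / 0.5 mm geometry that is
0.1171875 mm and 0.006866 mm³ (≈0.117 mm, ≈0.007 mm³). I/O is NIfTI-1 via
nibabel with voxel sizes in the header (affine diag(thickness, res_row,
res_col)); integer inputs are promoted to float losslessly, and load(save)
round-trips intensities bit-exactly. Scanner-native formats are assumed
converted upstream.

## Threshold segmentation

The reference statistics are the mean and n−1 SD pooled over all
brain-masked voxels of all lesion-free control subjects, per modality — a
cohort statistic, not per-animal or contralateral. Lesion voxels are those
inside the brain mask with intensity above mean + k·SD or below mean −
k·SD (default k = 2); hyper- and hypointense voxels both count, and T2 and
post-contrast T1 volumes are processed independently with their own
reference statistics. No minimum-cluster filter is applied by default; a
26-connectivity `min_cluster_voxels` option exists for noisy data. The
"semi-automatic" character of threshold volumetry in practice (an operator
confirming masks) is reduced here to: automatic thresholding plus an
optional user-supplied brain mask; there is no interactive editing, which
keeps the pipeline deterministic.

The default brain mask is Otsu's threshold, the largest connected
component, then a morphological closing with a 3³ structuring element —
standard, deterministic, and exact on the synthetic phantoms (Dice ≥ 0.99
against the generating ellipsoid).

### Noise bias and the corrected volume

With i.i.d. Gaussian brain intensities, thresholding at ±k SD flags an
expected fraction 2(1−Φ(k)) of noise voxels — 4.55% at k = 2, i.e. ~21 mm³
over a ~465 mm³ brain. On real images spatial correlation and operator
cleanup suppress most of this; on the synthetic phantoms it is fully
present, so `LesionResult` carries both the raw thresholded volume and
`volume_noise_corrected_mm3`, the raw volume minus the closed-form
expectation 2(1−Φ(k))·n_mask·v_vox (floored at zero). Recovery tests
assert the corrected volume against ground truth to within one
boundary-voxel shell of the lesion plus three binomial standard errors of
the false-positive count. The correction is unbiased only under the
homogeneous-Gaussian model; for real data it should be treated as an upper
bound on the noise contribution.

## Cohort statistics

Lesion volumes are modelled as a fixed-effects two-way ANOVA in scheme and
week (both categorical), fitted by OLS with sum-to-zero contrasts and Type
III sums of squares — chosen because realistic designs are unbalanced
(group sizes of 2–25) and arms can be censored. When censoring empties
scheme×week cells the interaction is inestimable; it is then dropped
automatically with a logged warning and the additive model is fitted. On
balanced designs the Type III F statistics coincide with the classic
sums-of-squares decomposition, which the tests verify against a
brute-force oracle at 1e−9 relative tolerance.

Post-hoc scheme contrasts use the Tukey–Kramer studentized-range procedure
(harmonic-mean sample sizes; classic Tukey HSD when balanced), applied
within each week so comparisons answer "which schemes differ at this
timepoint". Histology grades (ordinal 0–3: none/mild/moderate/severe) are
analysed as numeric responses in a one-way ANOVA with the same post-hoc —
an "ordinary ANOVA" convention; a nonparametric ordinal model is a
deliberate non-goal.

Repeated scans of the same animal enter as independent rows; within-animal
correlation is not modelled (no mixed effects). This matches common
practice for such designs but anti-conservatively inflates the effective
sample size — a caveat to keep in mind when interpreting p-values.

Under the null the scheme-factor test is exactly calibrated: the
acceptance suite measures a rejection rate within [0.035, 0.065] at
α = 0.05 over 1000 seeded replicates of a balanced 3×3×3 design.

## Synthetic phantoms and cohorts

A phantom is an ellipsoidal brain (default semi-axes 8×45×45 voxels,
~465 mm³ at study geometry) of i.i.d. Normal(μ, σ) voxels on a constant
background, with an optional lesion built by taking the N voxels nearest
the lesion centre in millimetre space (Euclidean distance → ellipsoid,
Chebyshev → block), N = round(target volume / voxel volume), so the
realized voxel count is exact and always recorded. A lesion reaching
outside the brain is rejected. Intensity scales are arbitrary units:
T2 μ = 500, σ = 25; post-contrast T1 μ = 400, σ = 20; lesions are offset
by +5 σ by default (hyperintense; a signed offset gives hypointense
lesions).

Longitudinal truth follows a saturating growth curve, 0 before onset and
plateau·(1 − e^(−rate·(t − onset))) after, with onset defaulting to week 3
(week 2 for the most severe arm), imaging at weeks {1, 2, 3, 4, 6}, and a
per-subject lognormal frailty (σ = 0.2) multiplying the plateau plus
Gaussian measurement noise (SD 0.3 mm³) on realized volumes. The built-in
study-like design has four fractionated arms (5×20, 10×10, 5×18, 10×9) and
single-fraction 80/90/100 Gy comparison arms; plateaus encode the
qualitative equivalences that motivate the analysis (100 Gy-total
fractionated ≈ 1×90, 90 Gy-total ≈ 1×80) and the 1×100 arm is censored
after week 2 (early sacrifice), which exercises the empty-cell path of the
ANOVA. Cohort generation is a pure function of (design, seed): per-subject
generators are spawned from a `SeedSequence`, and identical runs are
bit-identical.

What the generator does *not* emulate — spatially correlated noise,
partial-volume edges, bias fields, anatomy beyond an ellipsoid, contrast
kinetics — bounds what green tests mean: they validate the arithmetic and
statistical machinery of the pipeline, not its robustness to real-scanner
artefacts.

## Problem sizes and numerical choices

Tests run phantoms at a reduced 48×48×14 geometry (0.049 mm³ voxels) where
full resolution adds nothing, and at the full 128×128×21 geometry where
the check is about the study scale (noise rate, lesion recovery). The
null-calibration simulation uses 1000 replicates of a 27-observation
balanced design. Degenerate inputs fail loudly: zero-variance references,
empty masks and brains, single-level factors, singleton histology groups,
duplicate (subject, week, modality) keys. Group SDs are n−1; singleton
cells report SD as missing rather than zero.

## Known limitations

- The ±2 SD rule assumes approximately Gaussian normal-brain intensities;
  heavy-tailed or bimodal intensity distributions shift the effective
  false-positive rate.
- The noise-volume correction assumes spatially independent noise.
- Fixed-effects ANOVA ignores within-animal correlation across weeks.
- The LQ engine deliberately omits dose-protraction and repopulation
  corrections; it should not be used to compare schemes with very
  different overall treatment times.
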