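# Methods

`fetomics` re-implements, as a tested pipeline, the quantitative analysis
used to separate pseudoprogression (PSP) from early tumour progression (EP)
in glioma patients with equivocal MRI findings after temozolomide
chemoradiation, based on dynamic O-(2-[18F]fluoroethyl)-L-tyrosine (FET)
PET. This note documents the models, conventions and numerical choices; it
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The measurement model

A dynamic FET PET acquisition runs 0-40 min post-injection in 14 frames
(5 x 1, 5 x 3, 4 x 5 min) on a 2.0 x 2.0 x 2.4 mm voxel grid. All
intensities are standardized uptake values (SUV). Analysis operates on the
*summed image*, the duration-weighted mean of the four 5-minute frames
covering 20-40 min.

**Segmentation.** A 30 mm spherical background VOI (~14 mL) is placed in
normal-appearing contralesional brain; its center is an explicit argument
(in clinical practice this is a manual act, in the phantom it is supplied by
the generator). The tumour VOI is the set of voxels whose tumour-to-brain
ratio (TBR = voxel SUV / background mean SUV) is at least 1.6 — the
inclusive threshold reflects the biopsy-validated cut-off for vital tumour
in FET PET — restricted to the largest 26-connected component. Keeping one
component is our choice where the original auto-contouring is
under-specified; real tools seed from a click point, and a caller-supplied
search region is supported for the same reason. Data augmentation re-runs
the contour at TBR 1.4 and 1.8 (±10%), giving three nested VOIs per patient
and tripling a 34-patient cohort to 102 datasets.

**Conventional parameters.**

- TBRmean — tumour-VOI mean SUV / background mean SUV.
- TBRmax — mean SUV of a 16 mm sphere (~2 mL) centered on the hottest
  tumour voxel, divided by the background mean. It is a sphere *mean*, not
  the single max voxel. The sphere is not clipped to the tumour VOI
  (whether the original analysis clipped is unknowable; not clipping is the
  simpler reproducible rule). Argmax ties break toward the lowest linear
  index.
- TTP — mid-time of the frame in which the 16 mm-sphere time-activity curve
  (TAC) peaks; ties break toward the earlier frame. A TAC that is
  non-decreasing over the last three frames with its global maximum in the
  final frame is "steadily increasing" and TTP is the end of the
  acquisition (37.5 min on the mid-frame grid).
- Slope — ordinary-least-squares slope of the TAC over the 20-40 min frame
  mid-times, in SUV/h. Mid-times are the natural abscissae; the choice only
  matters for curvature, and the window is linear by construction in the
  phantom.

## The radiomics engine

944 features per VOI: 107 on the original summed image (18 first-order,
14 shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) and 93 (shape
excluded) on each of 9 filtered images — one Laplacian-of-Gaussian (sigma
0.5 mm, physical units) and 8 sub-bands of a single-level undecimated 3D
coif1 wavelet transform. Feature names follow
`<image>_<family>_<Feature>`.

Conventions that fix every value:

- **Discretization**: absolute binning, width 0.15 SUV, origin 0; bin index
  `floor(v / 0.15) + 1`, clipped below at 1 (filtered images can be
  negative; everything below the origin lands in bin 1). Absolute binning
  is standard for PET as it decouples texture from metabolic volume. A
  stated "64 bins between 0 and 10 SUV" elsewhere is arithmetically
  inconsistent with a 0.15 bin width (10/0.15 ≈ 66.7); the bin-width rule
  is authoritative here.
- **GLCM**: symmetric, distance 1, one matrix per each of the 13 unique 3D
  directions; features computed per direction and averaged. Degenerate
  single-level matrices: Correlation = 1, MCC = 1, Imc1 = Imc2 = 0.
- **GLRLM**: runs along the same 13 directions, features averaged.
- **GLSZM / GLDM**: 26-connected zones; GLDM dependence = 1 + number of
  26-neighbours with exactly the same gray level (alpha = 0).
- **NGTDM**: 26-neighbourhood means; voxels without any in-mask neighbour
  are excluded; Coarseness of a flat region is capped at 1e6, Busyness and
  Strength fall back to 0 when their denominators vanish.
- **First order**: Energy is `sum(v^2)` without intensity shift (SUV 0 is
  physically meaningful); Entropy/Uniformity use the discretized histogram;
  percentiles use linear interpolation; skewness/kurtosis are population
  moments (kurtosis not excess-corrected) and report 0 on constant VOIs.
- **Shape**: surface area and mesh volume from a marching-cubes
  triangulation; axis lengths are `4*sqrt(eigenvalue)` of the *sample*
  covariance (divisor n−1) of voxel-center coordinates in mm — this
  convention is load-bearing for the worked example (three collinear voxels
  2 mm apart give MajorAxisLength = 8 mm exactly). Maximum 2D diameters are
  measured between boundary-voxel centers within planes of constant z
  (Slice), y (Column) and x (Row). Single-voxel masks report 0 for axis
  features, with a warning.
- **LoG filter**: the separable decomposition of the Laplacian of a
  Gaussian is sampled analytically at voxel centers in physical units
  (truncated at 6 sigma, minimum radius 2 voxels); the second-derivative
  taps are mean-corrected to sum exactly to zero so constant images map to
  zero even when sigma is far below the voxel size (0.5 mm vs 2 mm here).
- **Wavelet**: `pywt.swtn` (stationary, so all sub-bands live on the input
  grid); odd axes are edge-padded to even and cropped back. "coif1" is the
  intended reading of the otherwise non-existent wavelet name "coifl".

Every texture matrix and feature is locked by brute-force oracles in the
test suite (independent pair/run/zone/dependence/neighbourhood enumeration
plus a plain-loop formulary, 200 random small instances, 1e-9).

## The synthetic cohort generator

No imaging data can ship with the package, so a phantom generator defines
the study conditions and gives every downstream stage known ground truth.
Per patient it draws:

- a peak TBR from a class-conditional normal — EP 2.6 ± 0.6, PSP 2.0 ± 0.3
  — truncated below at 1.85 so all three augmentation contours are
  non-empty; the location parameter is solved so the *class mean* is
  preserved despite truncation. Side effect: the truncation compresses the
  PSP dispersion to ~0.13 (EP ~0.47); the means and the 0.6 class contrast,
  which carry the diagnostic signal, are unaffected.
- a lesion: an ellipsoid (semi-axes 12.5-15 mm, mild anisotropy) with a
  flat plateau over 75% of each semi-axis and a cosine taper to background,
  placed in one hemisphere; the background VOI center mirrors it across the
  midplane. A multiplicative smooth Gaussian random field adds
  intralesional heterogeneity (EP: amplitude 0.25, correlation length 6 mm;
  PSP: 0.08, 12 mm) — EP lesions are textured, PSP lesions nearly
  homogeneous, which is the radiomics signal. A flat hot core (inner 60% of
  the plateau radius) keeps the hottest voxel at the lesion center so the
  16 mm sphere reads the plateau, and the profile is normalised so the
  noise-free summed TBR at the hottest voxel equals the drawn peak exactly.
- a TAC shape: piecewise-linear multiplicative profile, normalised to
  duration-weighted mean 1 over 20-40 min (hence summing reproduces the
  spatial profile exactly). "Early" curves peak in frames 8-10 then
  decline; "late" curves increase through the last frame. The 20-40 min
  slope is drawn per class (EP −0.2 ± 0.8, PSP +0.4 ± 0.5 SUV/h); for the
  late mode it is floored at +0.05 SUV/h so the curve genuinely increases
  (the realized value is recorded as ground truth).
- noise: zero-mean Gaussian per frame with sd
  `noise_sd_per_minute / sqrt(frame duration)` (default 0.15 SUV·min^1/2,
  i.e. ~15% of background in a 1-minute frame), mimicking count statistics;
  values are clipped at 0.

Grid 64 x 64 x 48 voxels at 2.0 x 2.0 x 2.4 mm; per-patient seeds derive
from `SeedSequence([cohort_seed, patient_index])`, so cohorts are
reproducible and extensible without perturbing earlier patients.

What the phantom does *not* emulate: scanner physics (attenuation, scatter,
OSEM reconstruction, partial volume), anatomy, realistic kinetic
compartment behaviour. Passing tests therefore demonstrate the correctness
and leak-safety of the pipeline under controlled contrast, not clinical
performance on real images.

## Statistics

Pseudoprogression is the positive class throughout. Direction conventions:
TBRmean/TBRmax predict PSP at or below the cut-off (inclusive), TTP at or
above (inclusive), slope strictly above — the only reading that reproduces
the published single-parameter table cell-for-cell from the cohort table.
Cut-off candidates are midpoints of adjacent distinct observed values; the
optimum maximises sensitivity x specificity, with ties broken toward higher
specificity, then the smaller cut-off. Parameter combinations are the
logical AND of the single-parameter rules at their individual cut-offs —
again adopted because it reproduces every published combination cell.

AUC is the rank-sum (Mann-Whitney) estimator with half-credit for ties.
Fisher's exact test is two-sided. The Mann-Whitney test uses the tie-aware
exact permutation distribution (dynamic programming over doubled midranks)
when both groups have at most 8 observations, and the tie-corrected normal
approximation without continuity correction otherwise. Kaplan-Meier medians
are the smallest time at which survival reaches 0.5 or below (evaluated
with a 1e-9 tolerance — at exactly S = 0.5 floating-point noise must not
push the median to the next event time); the log-rank test is the standard
1-df chi-square. Undefined ratios (zero denominators) are reported as
missing, never as 0.

## Classification workflow

The augmented feature table is split 70/30 at *patient* level, stratified
by diagnosis (with 18 EP + 16 PSP this gives 24 training patients / 72 rows
and 10 test patients, 5 per class / 30 rows). Grouping by patient is
mandatory: the three augmented rows of one patient are near-duplicates, and
any split or CV fold that separates them leaks. Feature selection is
recursive feature elimination with random-forest mean-decrease-in-impurity
importances, removing 10% of features per round down to at most 4 (a small
feature count is the point: interpretability and overfitting control at
n = 34). The classifier is a random forest; a small grid (trees 100/500,
depth unlimited/5) is chosen by patient-grouped 5-fold cross-validated
accuracy, training metrics are computed from the pooled hold-out
predictions, and the winner is refit on the full training side and applied
once to the untouched test rows. Row-level test metrics are the default
(matching the published report's n = 30); per-patient majority voting over
the three rows is available as an option. Rows are canonically sorted
before every fit so results are invariant to row order. The original
model-search step used an automated genetic-programming tool; since its
winning model was a random forest, this package fixes the classifier to a
random forest with the documented grid instead of re-running an open-ended
search.

## Problem sizes used in the checks

The acceptance script's two quantities (optimal TBRmax cut-off, PSP median
PFS) are exact computations on the packaged 34-patient table and run in
seconds. The stochastic checks use: 100 seeded 34-patient cohorts for the
class-separation test; one 34-patient cohort (seed 42, 102 VOIs) with 20
pipeline seeds for the sensitivity check and 20 patient-level label
permutations for the null calibration; 200 random instances of at most 6^3
voxels for the texture oracles. These sizes keep the full suite within a
routine CI run while leaving the binomial pass criteria (>= 90/100,
>= 16/20) well-powered.

## Known limitations

- The phantom's kinetic classes are deliberately schematic; TTP/slope carry
  class information by construction, whereas in patients the dynamic
  parameters did not separate the groups reliably.
- OS medians computed by Kaplan-Meier from the packaged table (38/15
  months) differ from the published 21/10, which match the naive median of
  uncensored event times; the package reports the KM values and does not
  assert the published ones.
- The rank-based AUC reproduces the published TBRmean/TBRmax AUCs exactly
  but not the TTP/slope values, and no Mann-Whitney convention reproduces
  both published group-comparison p-values simultaneously; the affected
  dynamic-parameter cells are reported, not matched.
- Radiomics values are fixed by this package's documented conventions;
  other engines differ in direction weighting, mesh construction and
  degenerate-case handling, so cross-engine feature values need not agree
  numerically.
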