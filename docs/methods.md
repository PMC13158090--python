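# Methods

## Problem and approach

Absolute signal units in contrast-enhanced breast MRI are not comparable
across scanners, coils, sequences, or patient positions, so tumor
conspicuity cannot be compared between exams by raw intensities. The
package instead quantifies *ratiometric* regional contrast: for each
case it compares the mean intensity of the segmented tumor against the
mean intensity of an equally sized boundary region of surrounding
tissue, using the Michelson (normalized) contrast

    C = (I_tumor - I_region) / (I_tumor + I_region)  ∈ [-1, 1],

which is invariant under any global positive rescaling of the image.
The boundary is further split into its adipose and fibroglandular
compartments so that contrast can be reported per tissue type; cohorts
of such per-case values are then compared with standard and
non-inferiority statistics.

## Per-case pipeline

**Equal-volume boundary shell.** Given a binary tumor mask on an
anisotropic voxel grid (spacing in mm), the Euclidean distance from
every non-tumor voxel center to the nearest tumor voxel center is
computed with a spacing-aware distance transform (anisotropy matters:
a 2 mm slice step must not be treated like a 1 mm in-plane step).
Voxels are admitted to the shell stratum by stratum — all voxels at one
distance enter together — until the shell's physical volume first
reaches the tumor's physical volume. This makes the construction
deterministic and mask-reproducible: the final stratum is included
whole, so the shell overshoots the tumor volume by less than one
stratum, and removing the outermost stratum always drops it below the
tumor volume (the minimality property the tests assert). An optional
body mask restricts eligibility (e.g. to exclude air near the skin);
if the eligible region is exhausted first, the shell is returned with a
`volume_deficit` flag rather than silently undersized.

**Tissue partition.** Shell voxels are split by Otsu's method: the
histogram of shell intensities (256 bins over [min, max] by default)
is scanned over all interior bin edges for the threshold maximizing the
between-class variance w0·w1·(mu0 − mu1)²; exact ties resolve to the
lowest edge. Voxels at or below the threshold are adipose, above it
fibroglandular — the assignment of sides is fixed by fat-suppression
physics (fat is dark, enhancing parenchyma bright on fat-saturated
post-contrast T1). Note one consequence of the lowest-tie rule: when
the two intensity modes are separated by an empty gap, the variance is
exactly constant across the gap and the selected threshold is the gap's
lower edge; the resulting labels are identical to any other in-gap
choice. Pectoral muscle inside the shell is tolerated in the
fibroglandular class. A constant-intensity shell has no threshold; it
is labeled entirely as one tissue by comparing its mean to the tumor
mean and flagged `degenerate_partition`. The fibroglandular boundary
composition is the fibroglandular share of the shell's physical volume.

**Metrics.** Per case the package reports tumor-to-boundary,
tumor-to-adipose, and tumor-to-fibroglandular Michelson contrasts;
shell composition; SNR and CNR; voxelwise ROC AUCs; and tumor
volume, maximum extent, surface area, and sphericity. SNR and CNR need
a noise scale sigma: preferred is the standard deviation of air voxels
outside the body mask; the fallback is a robust sigma (1.4826 × MAD) of
the darkest decile of shell intensities, a heuristic that is biased low
when the darkest tissue carries structure and is therefore only a
fallback. SNR_region = mean_region/sigma, CNR = (mean_tumor −
mean_tissue)/sigma. The AUC treats voxel intensity as a score with
tumor voxels as positives and one tissue compartment as negatives; it
is computed by ranks with ties counted 1/2 and equals the Mann-Whitney
U statistic divided by n1·n2 (asserted identically in tests). Metrics
undefined for a case (empty compartment, no noise estimate, zero
contrast denominator) are reported as missing with an explicit flag,
never as zero.

**Shape metrics.** Surface area uses exposed-face counting (faces of
mask voxels adjoining non-mask voxels or the grid border, weighted by
their physical face area). This is deterministic and adequate for a
relative shape index, but it overestimates smooth surfaces: the
face-count area of a digitized ball converges to 1.5 × the smooth
sphere area, so the sphericity pi^(1/3)(6V)^(2/3)/A of a ball converges
to 2/3 rather than 1. Sphericity values are therefore comparable within
this package but not with mesh-based definitions. Maximum extent is the
exact largest pairwise distance between surface-voxel centers (via the
convex hull for large surfaces).

## Cohort statistics

Primary comparisons are Welch two-sample t-tests (unequal variances,
alpha = 0.05) with Welch–Satterthwaite degrees of freedom and 95%
confidence intervals on the mean difference. Non-inferiority of a new
acquisition against a reference is tested one-sided at alpha = 0.025 by
shifting the Welch statistic by the margin (default −0.1 normalized
contrast units, i.e. a 0.1 contrast drop is the largest tolerable
deficit): H0: mu_new − mu_ref ≤ margin. Rejection is declared when
p < alpha, which coincides exactly with the lower bound of the
two-sided 95% CI lying above the margin; the package asserts this
duality rather than leaving the two phrasings to drift apart. Verdicts
are `non_inferior` or `inferior_not_shown` — a failure to reject never
demonstrates inferiority.

Post-hoc power is evaluated at the observed effect through the
noncentral t distribution (Welch df by default; pooled df available for
cross-checking against pooled-df calculators). For two-sided tests it
is a monotone transform of the p-value and is reported as descriptive
only. Mann-Whitney U tests (exact for small tie-free samples,
tie-corrected normal approximation otherwise) accompany every pairwise
comparison because the cohort sizes may be very unequal. Normality is
checked with a one-sample Kolmogorov–Smirnov test against a normal with
the sample's own mean and SD; with estimated parameters the classical
p-value is conservative, and a Lilliefors-corrected variant is provided.
Pearson correlations (boundary contrast vs. shell composition, tumor
volume, maximum extent, sphericity) carry Fisher-z 95% intervals,
tanh(arctanh r ± z0.975/√(n−3)). The tumor-to-boundary contrast itself
is excluded from cross-cohort testing — it confounds enhancement with
boundary composition — and is analyzed through these correlations
instead. Missing per-case metrics are excluded listwise per metric. No
multiple-testing correction is applied.

## Synthetic phantoms

The generator produces the study conditions the framework is tested
under: an ellipsoidal body, an ellipsoidal tumor (default semi-axes
7 × 6 × 5 mm, i.e. a >1 cm lesion) on a 48 × 48 × 32 grid at
1 × 1 × 2 mm spacing (typical in-plane resolution and slice thickness
of axial 3D gradient-echo breast protocols), and a peritumoral mixture
of dark adipose and bright fibroglandular tissue. Default means are
tumor 400, fibroglandular 150, adipose 30, air 2 (arbitrary units,
ordered as on fat-suppressed post-contrast T1), with additive Gaussian
noise sigma = 10 (moderate-SNR magnitude imaging; a Rician option
exists for low-SNR realism). Tissue texture is a Gaussian random field
smoothed to a 1.5 mm correlation length and thresholded at the quantile
that makes the equal-volume boundary shell hit the requested
fibroglandular fraction exactly (to one voxel); the same threshold
extends the texture continuously through the rest of the body. Defining
the controlled neighborhood as the shell itself keeps ground truth
exact where the pipeline measures, so recovery tests isolate classifier
error from spatial sampling noise.

Cohorts jitter per-case intensity means (SD 25/12/4 for
tumor/fibroglandular/adipose), tumor semi-axes (±12%), and shell
composition (uniform 0.2–0.6). A delayed-acquisition cohort applies a
washout factor w ∈ [0, 1]: the tumor mean decays linearly toward the
fibroglandular mean, mean_tumor → mean_fibro + (mean_tumor −
mean_fibro)(1 − w), while an optional persistence factor inflates the
fibroglandular mean — mimicking gadolinium kinetics in which tumor
signal washes out at later timepoints while parenchymal enhancement
persists. Case randomness derives only from the cohort seed and case
index, so two cohorts sharing a seed are matched "patients" differing
solely through w (a paired early/delayed design), and w = 0 reproduces
the early cohort bit-exactly. Expected per-case contrasts follow
analytically from the effective means and are emitted in the
ground-truth table.

What the phantoms do not emulate: anatomically realistic breast
morphology, bias fields, motion or streaking artifacts, partial-volume
boundaries, pharmacokinetic enhancement curves, or prone–supine
deformation. Passing tests therefore demonstrate the correctness and
calibration of the measurement and statistical machinery under known
ground truth — not segmentation robustness on clinical images.

## Numerical choices and degenerate inputs

* Volume/mask grids must agree in shape, and header spacings within
  1e-3 mm per axis; disagreement is an error, not a warning, because a
  silent mismatch corrupts every mm³ quantity downstream.
* Masks are voxel-aligned and boolean; no sub-voxel membership, no
  resampling, no reorientation (the method is orientation-agnostic).
* Distance strata are compared exactly (floating-point equality of EDT
  values); stratum inclusion is all-or-nothing.
* Otsu ties break to the lowest qualifying edge; the partition rule is
  `<= threshold` → adipose.
* Zero-variance groups in Welch tests are degenerate: p = 1 for equal
  means, p = 0 otherwise. The noncentral-t far tail, where scipy
  returns NaN, is mapped to its limiting mass of zero.
* A Pearson r of exactly ±1 gets a point confidence interval at ±1.
* Empty compartments, unestimable noise, and undefined contrasts
  propagate as flags plus missing values.

## Problem sizes used in the bundled analyses

The test suite and the acceptance script run entirely on synthetic
phantoms: grids of 24³–48·48·32 voxels, cohorts of 4–78 cases
(the shipped synthetic study uses 78 early-phase reference cases, 17
independent early-phase cases, and 61 delayed cases at w = 0.5,
mirroring a realistic enrollment imbalance across arms), 10,000
Monte-Carlo replicates for the type-I-error calibration of the
non-inferiority test, and 1,000 replicates for correlation-interval
coverage. These sizes give stable statistics while keeping a full run
in the order of seconds to a few minutes on one CPU.

## Known limitations

* Otsu always yields a two-class split; on a genuinely single-tissue
  (but noisy) shell it will split the noise distribution itself, so
  composition estimates for extreme (all-fat or all-dense) boundaries
  are meaningful only when a true bimodal mixture exists. Only exactly
  constant shells are detected as degenerate.
* The decile-based fallback noise estimate is biased; SNR/CNR from it
  should be compared only within a consistent noise mode.
* Face-count sphericity is scale-consistent but not comparable to
  mesh-based sphericity (ball limit 2/3, see above).
* Post-hoc power is descriptive; it must not be read as design power.
* The washout model is linear in w by construction; it is a mechanism
  stand-in, not a pharmacokinetic model.
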