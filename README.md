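# regioncontrast

Quantitative comparison of regional tumor contrast across
contrast-enhanced breast MRI exams.

## The problem

Absolute signal intensities in contrast-enhanced breast MRI are not
comparable between scanners, coils, sequences, or patient positions
(prone vs. supine), so the question "is tumor conspicuity in this
acquisition as good as in that one?" cannot be answered from raw
units. `regioncontrast` answers it ratiometrically. For each case —
an intensity volume plus a radiologist's binary tumor segmentation —
it measures the normalized (Michelson) contrast between the tumor and
an equally sized shell of surrounding tissue:

    C = (I_tumor − I_region) / (I_tumor + I_region)  ∈ [−1, 1]

where I_tumor and I_region are mean intensities. C is invariant under
global intensity rescaling, which makes it comparable across exams.
The boundary shell is grown outward from the tumor surface in
spacing-aware Euclidean distance until its physical volume first
matches the tumor's (an equal-volume comparison), then split into its
dark adipose and bright fibroglandular compartments by Otsu
thresholding, so contrast is reported per tissue type. Companion
metrics (SNR, CNR, voxelwise ROC AUC, tumor volume/extent/sphericity)
and a cohort-level statistical framework — Welch and Mann-Whitney
tests, one-sided non-inferiority tests with a margin in contrast units
(default −0.1), post-hoc power, and Pearson correlations with Fisher
95% CIs — complete the pipeline.

The intended users are imaging scientists evaluating investigational
acquisition protocols (e.g. supine surgical-planning MRI against
standard-of-care prone MRI, or delayed single-session re-imaging
against early-phase imaging) who need a scanner-independent,
reproducible measure of tumor-to-tissue conspicuity.

A synthetic phantom generator with exact ground truth (ellipsoidal
tumor, textured adipose/fibroglandular surround, air background,
Gaussian or Rician noise, and a contrast-washout mechanism for delayed
acquisitions) makes every stage testable without clinical data. See
`docs/methods.md` for the full model description.

## Worked example

```python
from regioncontrast import PhantomSpec, make_phantom, RunConfig
from regioncontrast.pipeline import analyze_phantom_case

case = make_phantom(PhantomSpec(seed=3))          # 48x48x32, 1x1x2 mm
report = analyze_phantom_case(RunConfig(), case)
print(f"tumor-to-boundary contrast:       {report.contrast_tumor_boundary:.3f}")
print(f"tumor-to-fibroglandular contrast: {report.contrast_tumor_fibro:.3f}")
print(f"tumor-to-adipose contrast:        {report.contrast_tumor_adipose:.3f}")
print(f"fibroglandular boundary composition: {report.fibro_fraction:.1%}")
print(f"Otsu threshold: {report.otsu_threshold:.1f}   noise sigma: {report.noise_sigma:.1f}")
print(f"CNR tumor-fibro: {report.cnr_tumor_fibro:.1f}   AUC tumor-fibro: {report.auc_tumor_fibro:.3f}")
print(f"tumor volume: {report.shape.volume_mm3:.0f} mm^3   shell volume: {report.shell_volume_mm3:.0f} mm^3")
```

prints

```
tumor-to-boundary contrast:       0.672
tumor-to-fibroglandular contrast: 0.453
tumor-to-adipose contrast:        0.859
fibroglandular boundary composition: 40.0%
Otsu threshold: 67.1   noise sigma: 10.0
CNR tumor-fibro: 25.1   AUC tumor-fibro: 1.000
tumor volume: 910 mm^3   shell volume: 916 mm^3
```

Reading: the tumor (mean ≈ 400) stands out strongly from the dark
adipose surround (contrast 0.86) and moderately from the enhancing
fibroglandular tissue (0.45); the overall boundary contrast (0.67)
falls between the two because the shell is a 40/60 fibroglandular/
adipose mixture. The shell volume (916 mm³) matches the tumor volume
(910 mm³) to within one distance stratum — that near-equality is the
equal-volume construction working.

Cohort-level use takes a manifest CSV (`case_id, cohort_label,
volume_path, tumor_mask_path[, body_mask_path]`) pointing at NIfTI
files:

```bash
regioncontrast simulate-cohorts --out-dir data --n-early 30 --n-delayed 30 --washout 0.5 --seed 1
regioncontrast analyze-cohort data/manifest.csv --out-dir out
regioncontrast compare out/cases.csv --out-dir out --reference early
```

`out/comparisons.csv` holds per-metric Welch/MWU/KS results,
`out/forest.csv` the non-inferiority rows (difference, 95% CI, margin,
verdict) ready for a forest plot, and `out/correlations.csv` the
boundary-contrast-vs-composition and size/shape correlations. In this
delayed-cohort example, tumor-to-fibroglandular contrast comes out
inferior (washed-out tumor, persistent parenchyma) while
tumor-to-adipose contrast stays non-inferior.

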