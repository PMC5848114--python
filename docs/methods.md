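# Methods

## The two-compartment model

A voxel's CT number is `CTN = (μ̄_mix/μ̃_H2O − 1)·1000`, with
`μ̄_mix = v_a·μ̃_a + (1 − v_a)·μ̃_b` for a two-material mixture whose
component volume fractions are `v_a` and `1 − v_a` (spectrum-weighted
attenuation coefficients μ̃). Solving for the volume fraction, the
`CTN/1000 + 1` terms cancel and

```
v_a = (CTN_mix − CTN_b) / (CTN_a − CTN_b).
```

With cortical-bone-equivalent material as compartment *a* and
marrow-equivalent water as compartment *b*, `v_a` is the bone volume
fraction (BVF) and `vBMD = BVF · ρ_cor`. The weight-fraction relation
`w_a = v_a·ρ_a/ρ_mix` is provided for completeness; the mixture density
cancels out of the vBMD expression, so the inversion needs only the two
reference CT numbers and `ρ_cor`.

**Semantics of `ρ_cor`.** It is the *mineral-equivalent* density of the
calibration phantom — the K₂HPO₄ mass per solution volume (0.533 g/cm³ in
the bundled calibration) — not the solution's physical mass density. This
is the only reading under which the phantom's own CT number inverts to its
labelled 0.533 g/cm³.

**Assumptions.** (i) The scan's effective spectrum matches the calibration
scan at the same kVp (hence per-kVp entries); (ii) every voxel is a
two-material mixture — voxels of real cortical bone or of denser phantom
material (e.g. a 0.800 g/cm³ wall) violate the bound `BVF ≤ 1`. The
inversion therefore returns **raw, unclamped** values by default, and the
optional clamp records exactly which voxels fell outside [0, 1]. Published
recoveries of 0.800 g/cm³ walls with a 0.533 g/cm³ calibration are only
possible unclamped, so unclamped is the faithful default.

**ACR classification.** Osteoporosis strictly below 80 mg/cm³; osteopenia
on the closed interval [80, 120] mg/cm³ ("between 80 and 120" is read as
inclusive on both ends so boundary behaviour is well defined); normal
above. Internal unit is g/cm³; mg/cm³ appears only at this boundary
(exact ×1000).

## Calibration

`roi_stats` uses pixel-center membership (half-open rectangle edges) so ROI
masks are deterministic and resolution-independent, and the sample SD
(n − 1), the standard choice for ROI statistics. The bundled default table
carries water/cortical reference means of −11.1/982.2, 2.1/830.0 and
8.7/739.5 HU at 80, 100 and 120 kVp with their ROI SDs (30.3/41.4,
23.7/27.2, 13.8/16.4 HU). The cortical-phantom ROI in the reference
protocol is 30 mm × 30 mm; the water ROI, not separately specified, uses
the same default. Calibration files are YAML, one block per kVp
(`ctn_mar`, `ctn_mar_sd`, `ctn_cor`, `ctn_cor_sd`, `rho_cor`).

## Synthetic phantoms

The simulator exists so every downstream operation can be tested against
known ground truth. Scenes are ordered shape lists (painter's order) with
nominal vBMD or explicit HU; rendering supersamples each pixel
(default 8×8) and box-averages down, so boundary pixels carry the
partial-volume mixing that motivates interior-eroded ROIs in the tests.
Gaussian i.i.d. HU noise is added from a seeded generator; default SDs
follow the per-kVp cortical-scan values above. The default forward model is
*calibrated* mode (affine in BVF — exactly what the inversion inverts);
attenuation mode is available for users supplying μ values.

Beam hardening is emulated, not simulated: inside shapes whose CT number
exceeds 400 HU, the rendered value is scaled by `1 − a·(1 − r/R)` with
`a = cupping_amplitude/1000` — a monotone radial deficit producing the
qualitative center-of-dense-object underestimation seen in low-kVp scans.
No projection/reconstruction physics, correlated noise, scatter or
metal artifacts are modelled, and the toy femur is schematic (concentric
disks), not anatomical. Passing tests therefore demonstrate correctness of
the *inversion chain* under the model's own assumptions plus noise and
partial volume — not robustness to reconstruction artifacts or anatomy.

Geometry choices where the reference protocol gives none: vials are 20 mm
in diameter with 12 mm ROIs (≥400 pixels at 0.5 mm spacing); the forearm
phantom is rendered as the longitudinal plane through its four stacked
HA sections (0.194/0.103/0.054/0 g/cm³, each 20 mm × 11.6 mm inside a
1.2 mm wall of 0.800 g/cm³) and two water inserts, inside a 60 mm
water-equivalent body at 0.25 mm spacing.

## Femoral-neck protocol

Segmentation thresholds the whole slice at 250 HU, fills holes, and keeps
the largest connected component (or the component overlapping a supplied
ROI). Hole filling is essential: trabecular interiors near 0.17 g/cm³ sit
*below* 250 HU, so the threshold alone finds only the cortical shell; the
filled contour includes marrow and nonosseous voids, and averaging over it
is what lets a neck mean reflect such voids. Averaging only
supra-threshold voxels (available as `bone_only`) biases the neck vBMD
upward and is kept for sensitivity analysis.

Slice selection scores each coronal slice by filled-bone area inside a
neck region and picks the argmax plus its two neighbours; ties go to the
lower index (flagged), and a boundary maximum returns the two available
neighbours with a flag. Because the drawn VOI may deliberately exclude the
shell, the area-ranking region (`selection_roi`) can be supplied
separately from the averaging VOI; it defaults to the same ROI. The VOI
mean CT number is converted once — the inversion is affine, so
mean-then-convert equals convert-then-mean exactly.

## Statistics

Pearson/least-squares fits use the standard two-sided t test with n − 2
degrees of freedom. The age-related bone-loss rate is
`−slope / baseline · 100` %/year with the group's mean vBMD as the default
baseline (the percentage's reference point is not fixed by convention;
the baseline is an explicit argument). ICC(3,1) — two-way mixed model,
single measurement, consistency — is computed from the two-way ANOVA,
`(BMS − EMS)/(BMS + (k − 1)·EMS)`, with the classical F-bound 95% CI;
consistency means fixed per-rater offsets do not reduce the coefficient.
Rating tables with missing cells are rejected rather than imputed. When
the residual mean square underflows relative to the between-subject mean
square (raters identical up to rounding), the ICC is reported as exactly 1.

The synthetic cohort generator draws ages uniformly and builds vBMD (and
aBMD) with exact target correlations in the population sense; it emulates
a cross-sectional study only — no longitudinal change, menopause status or
measurement-device effects.

## Problem sizes and numerics

Builtin scenes render in seconds on one core: 80×360 px (vials), 320×320
(forearm), 200×200 per femur slice, supersample 8. Acceptance runs use
seven-slice femur volumes and a 28-subject cohort (17 male/11 female, the
reference study's composition). Round-trip identities hold to 1e-9
(noise-free); degenerate inputs (coincident calibration references,
inverted water/cortical scans, empty segmentations, zero-variance
regressions) raise typed errors rather than propagating NaNs.

## Known limitations

- Voxels denser than the calibration phantom break the BVF ≤ 1 assumption;
  values are reported raw and flagged, not corrected.
- The cupping model is directional-only; it is not a beam-hardening
  correction and should not be used to calibrate one.
- Clinical-scale correlations (vBMD vs DXA aBMD, observer ICCs) can only
  be demonstrated here on synthetic cohorts with known ground truth.
- DICOM support covers uncompressed CT Image Storage with rescale tags;
  compressed transfer syntaxes depend on the pydicom runtime.
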