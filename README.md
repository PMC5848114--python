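# tcmbmd

Volumetric bone mineral density (vBMD) from CT images via a two-compartment
model (TCM).

Dual-energy X-ray absorptiometry reports an *areal* BMD (g/cm²) that is
confounded by bone thickness and body size and cannot show nonosseous areas
inside trabecular bone. Quantitative-CT-style methods instead estimate the
*volumetric* BMD (g/cm³). `tcmbmd` implements a simple and auditable route:
each voxel is modelled as a two-material mixture of cortical-bone-equivalent
material (a K₂HPO₄ aqueous solution in the reference calibration) and
marrow-equivalent material (water). Because a CT number is affine in the
volume fraction of either compartment, a single per-kVp linear calibration
inverts every voxel:

```
BVF  = (CTN_mix − CTN_mar) / (CTN_cor − CTN_mar)
vBMD = BVF · ρ_cor
```

where `CTN_mar` and `CTN_cor` are reference CT numbers (HU) measured on a
water vial and on a cortical-equivalent phantom of mineral-equivalent
density `ρ_cor` (0.533 g/cm³ in the bundled calibration), and `BVF` is the
bone volume fraction. Diagnostic classification follows the ACR QCT
cut-offs: osteoporosis below 80 mg/cm³, osteopenia between 80 and
120 mg/cm³.

The package is aimed at medical-physics and bone-densitometry researchers
who want the whole validation chain to be reproducible without clinical
data: it bundles a synthetic phantom simulator (vial arrays, a standard
forearm phantom, a toy femoral neck) driven by the same forward model the
inversion assumes, plus the femoral-neck VOI protocol and the reliability
statistics used to validate such pipelines.

## Worked example

Render the seven-vial calibration array at 120 kVp with realistic image
noise (σ = 16.4 HU), convert each vial ROI back to vBMD, and classify it:

```python
from tcmbmd import default_calibration, ctn_to_bvf_vbmd, roi_stats, classify_acr
from tcmbmd.phantom import (ForwardModel, builtin_specs, render_phantom,
                            seven_vial_rois, SEVEN_VIAL_DENSITIES)

entry = default_calibration()[120]
model = ForwardModel.from_calibration(entry)
image = render_phantom(builtin_specs("seven_vials", kvp=120, seed=7), model)

for roi, nominal in zip(seven_vial_rois(), SEVEN_VIAL_DENSITIES):
    stats = roi_stats(image, roi)
    vbmd = float(ctn_to_bvf_vbmd(stats.mean, entry).vbmd)
    print(f"nominal {nominal:.3f}  recovered {vbmd:.3f} g/cm^3  "
          f"({classify_acr(vbmd).label})")
```

prints

```
nominal 0.135  recovered 0.135 g/cm^3  (normal)
nominal 0.202  recovered 0.202 g/cm^3  (normal)
nominal 0.267  recovered 0.267 g/cm^3  (normal)
nominal 0.300  recovered 0.300 g/cm^3  (normal)
nominal 0.344  recovered 0.345 g/cm^3  (normal)
nominal 0.401  recovered 0.401 g/cm^3  (normal)
nominal 0.467  recovered 0.468 g/cm^3  (normal)
```

i.e. the linear inversion recovers the nominal densities to ≲0.001 g/cm³
under ROI averaging — comfortably inside the 0.009/0.019 g/cm³
(mean/max) error envelope a physical scan of the same array exhibits.

The same operations are available from a shell:

```sh
tcmbmd simulate seven_vials --seed 7 --out vials.npz
tcmbmd convert vials.npz --out converted --roi circle:39.5,35.5,12
tcmbmd femur volume.npz --neck-roi roi.yaml
tcmbmd icc ratings.csv
```

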