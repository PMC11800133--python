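# alps-glymph

A tested Python pipeline for **DTI-ALPS** analysis — "diffusion tensor image
analysis along the perivascular space" — the diffusion-MRI index used as a
noninvasive marker of glymphatic (perivascular waste-clearance) function,
here in the setting of acute spontaneous intracerebral hemorrhage (sICH).

It is aimed at neuroimaging researchers who want a reproducible, fully
synthetic testbed for the ALPS measurement chain: because patient-level DWI
and outcome data in this area are rarely deposited, the package pairs every
analysis stage with a simulator whose ground truth is known exactly.

## The index

At the level of the lateral-ventricle body, the deep medullary veins run
left–right (x), perpendicular to the projection fibers (principal diffusion
axis inferior–superior, z) and the association fibers (principal axis
anterior–posterior, y). Water movement along the perivascular spaces of
those veins adds x-diffusivity in both tracts, so with 5 mm ROIs placed on
each tract on a color-FA map:

```
ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)
```

An index near 1 means no preferential perivascular diffusion; healthy adults
measure about 1.46 ± 0.22. In acute sICH the hemisphere carrying the
hematoma ("ipsilateral") drops to about 1.34 ± 0.24, the index correlates
negatively with hemorrhage and edema volumes, and a higher ipsilateral index
independently predicts a favorable 90-day outcome (odds ratio ≈ 1.686 per
0.1 increase, adjusted for age, sex, baseline NIHSS and hemorrhage volume).

## What's inside

- `alps_glymph.phantom` — synthetic DWI phantom (single-tensor signal model,
  Rician noise, periventricular ALPS geometry, nested hematoma/edema
  lesions) with exact analytic ground truth;
- `alps_glymph.tensorfit` — log-linear least-squares tensor fitting, FA,
  direction-encoded color FA, and the Dxx/Dyy/Dzz maps;
- `alps_glymph.alpsindex` — ROI extraction, the ALPS ratio, and
  ipsilateral/contralateral lateralization against the lesion side;
- `alps_glymph.volumetry` — hematoma/edema volumes and the relative edema
  ratio (edema / hemorrhage) from binary masks;
- `alps_glymph.cohort` — a cohort simulator (Gaussian copula with
  moment-matched marginals, calibrated logistic outcome model);
- `alps_glymph.stats` / `alps_glymph.reports` — the statistical battery:
  normality screening, pooled/Welch t-tests (raw or summary form),
  Pearson/Spearman correlation, 2×2 tests, linear and logistic regression
  with per-0.1 odds-ratio scaling;
- `alps-glymph` CLI — `simulate-dwi`, `simulate-cohort`, `fit-tensor`,
  `alps`, `volumes`, `stats`, `run-all`.

## Worked example

```python
import numpy as np
from alps_glymph import (PhantomSpec, build_alps_phantom,
                         fit_tensor_loglinear, axis_diffusivities)
from alps_glymph.alpsindex import ROISpec, alps_from_maps

# 64x64x16 phantom at 1.7x1.7x2 mm, b=1000 s/mm^2, 30 directions,
# 2% Rician noise (S0 = 1000)
spec = PhantomSpec(shape=(64, 64, 16), noise_sigma=20.0, seed=42)
dwi, truth = build_alps_phantom(spec)

field = fit_tensor_loglinear(dwi)
dxx, dyy, dzz = axis_diffusivities(field)
rois = [ROISpec(h, f, c) for (h, f), c in truth.roi_centers.items()]
result, means = alps_from_maps(dxx, dyy, dzz, rois,
                               spec.voxel_size_mm, lesion_side="left")
print(f"analytic ALPS (left/right): "
      f"{truth.analytic_alps['left']:.3f} / {truth.analytic_alps['right']:.3f}")
print(f"measured ALPS ipsilateral:  {result.ipsilateral:.3f}")
print(f"measured ALPS contralateral: {result.contralateral:.3f}")
print(f"measured ALPS average:       {result.average:.3f}")
```

prints

```
analytic ALPS (left/right): 1.460 / 1.460
measured ALPS ipsilateral:  1.438
measured ALPS contralateral: 1.459
measured ALPS average:       1.449
```

The default phantom tensors are chosen so a healthy hemisphere has an
analytic index of exactly (1.15 + 1.04) / (0.80 + 0.70) = 1.46; with 2%
magnitude noise, 5 mm ROIs recover it to a few hundredths.

An end-to-end run (phantom → fit → ALPS → volumetry → cohort → Table-shaped
reports, with a JSON manifest and per-stage seeds):

```sh
alps-glymph run-all --out runs/demo --seed 7
```

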