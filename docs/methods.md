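# Methods

## Signal model and phantom

The phantom uses the single-tensor diffusion model
`S_i = S0 * exp(-b_i * g_i^T D g_i)` per voxel, with a single-shell
acquisition of 30 directions at b = 1000 s/mm² plus one b = 0 volume
(defaults chosen to mirror a routine clinical DTI protocol; voxel size
1.7 × 1.7 × 2 mm, default grid 96 × 96 × 40, axis-aligned RAS affine with
the world origin at the volume center). Gradient directions come from a
deterministic spherical Fibonacci lattice restricted to the upper
hemisphere: diffusion encoding is antipodally symmetric, and the
hemispheric lattice keeps the 7-column log-linear design full-rank down to
the identifiability floor of six directions, which a full-sphere lattice
does not (its near-antipodal pairs are degenerate at small n). Slice gaps
are not modeled; the grid is contiguous, which simplifies volumetry and is
conservative for ROI placement.

The geometry emulates the periventricular anatomy the ALPS protocol reads:
a CSF-filled ventricle slab at the midline, flanked on each side by a
projection-fiber band (principal axis z) and an association-fiber band
(principal axis y), all spanning a central slab of slices. Default tissue
tensors (mm²/s) are phantom parameters, not anatomical claims:
CSF isotropic 3.0e-3, background isotropic 0.7e-3,
projection diag(1.15e-3, 0.8e-3, 1.7e-3),
association diag(1.04e-3, 1.7e-3, 0.7e-3). The fiber diagonals are set so
the analytic healthy index is exactly (1.15 + 1.04)/(0.80 + 0.70) = 1.46,
the center of the healthy-adult range, making phantom-level and
cohort-level simulations commensurate.

Ground truth recorded with each phantom: the per-voxel tensor field, the
analytic per-hemisphere index computed from the assigned diagonals, and ROI
centers. ROI centers are the most interior voxel of each fiber band on the
central ("deep-medullary-vein") slice, found by an in-plane Euclidean
distance transform — this guarantees a 5 mm disc stays inside its band
whenever the band is wide enough, and makes the truth independent of
arbitrary centroid rounding.

Noise is Rician: `sqrt((S + n1)^2 + n2^2)` with `n1, n2 ~ N(0, sigma)`,
the magnitude-MRI noise model; `sigma` is configured relative to S0 (2% of
S0 in the oracle checks). Nested hematoma/total-lesion ellipsoids can be
painted into the region map (hematoma isotropic 0.4e-3, edema isotropic
1.2e-3); an axis-aligned containment check rejects non-nested
configurations.

## Tensor estimation

Log-linear ordinary least squares: `ln S_i = ln S0 - b_i g_i^T D g_i` is
linear in the six unique tensor components and ln S0 and is solved for all
masked voxels at once through the pseudoinverse of the shared design
matrix. A weighted variant (weights proportional to the squared signal, the
first-order variance correction for log-transformed magnitude data) is
available by flag; it is solved per voxel by batched SVD because the
weighted normal equations are ill-conditioned (design columns span ~6
orders of magnitude). Signals ≤ 0 are clamped to 1e-6 of the voxel's
maximum before the log and counted in the run log; all-zero voxels are
dropped from the fit mask with a warning. Negative eigenvalues are clamped
to zero for FA and color-FA only — the stored tensor keeps the raw fit so
Dxx/Dyy/Dzz stay faithful. Eigenvectors get a deterministic sign (first
nonzero component positive); exact eigenvalue ties (isotropy) leave the
basis arbitrary, which is harmless because FA is then 0.

FA is `sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||`, zero for an
all-zero triplet; color FA is `FA * |v1|` per channel, clipped to [0, 1].
Axis diffusivities are the tensor diagonal in canonical RAS axes; loaded
NIfTI volumes are reoriented to closest-canonical before any axis-labelled
computation, matching the ALPS convention (x left–right, y
anterior–posterior, z inferior–superior).

## ROI extraction and the index

ROI membership is voxel-center-in-disc on a single axial slice (ROIs are
drawn on 2-D color-FA images in practice), native grid, no partial-volume
weighting. The index is exactly
`(Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)` on the ROI means; a
non-positive denominator is an error. Measurement is always attempted
bilaterally. A unilateral supratentorial lesion maps the lesion hemisphere
to "ipsilateral"; subtentorial or absent lesions carry only the average of
the two sides (per-subject mean of hemispheres, which is also how the
healthy-control "average" index is defined here). ROI placement is an
input file (JSON of center voxel, hemisphere, fiber class, diameter),
mirroring manual placement; `suggest_roi_centers` offers an advisory
starting point by maximizing z-dominant / y-dominant color-FA in a
periventricular band, but its output is meant to be reviewed.

## Volumetry

Volumes are nonzero-voxel counts × voxel volume (from the affine's column
norms; a disagreeing header pixdim is logged and the affine wins).
Hematoma (susceptibility-weighted contrast) and total lesion (T2 contrast)
may live on different grids, so volumes are computed natively and combined
as scalars: edema = total − hematoma, floored at zero with a warning when
cross-modality delineations disagree (the floor is this package's choice;
the behavior of a negative difference is otherwise undefined). The
relative edema ratio is edema/hemorrhage and is undefined at zero
hemorrhage.

## Cohort simulator

Continuous variables are drawn from a Gaussian copula. Marginals:
normal for the ALPS indices and age; zero-truncated normal, moment-matched
so the truncated distribution reproduces the configured mean ± SD, for
NIHSS and disease duration; moment-matched lognormal for hemorrhage and
edema volumes. The lognormal choice is forced for edema, not merely
cosmetic: a zero-truncated normal cannot reach SD/mean ≥ 1 (its
exponential-tail limit), and the edema target is 24.2 ± 26.2 mL
(SD/mean ≈ 1.08); SD ≈ mean for both volumes indicates right skew anyway.
The "proportion truncated" logged for truncated-normal marginals is the
underlying normal mass below zero.

Because non-normal marginals attenuate the copula correlation, each latent
correlation is calibrated by root finding so the **output** Pearson
correlation hits its target, with the pair correlation under a given latent
value evaluated by two-dimensional Gauss–Hermite quadrature (64 nodes per
axis). Unreachable targets (beyond the attenuation bound) and
non-positive-definite matrices are reported as errors. Defaults: ipsilateral
ALPS 1.34 ± 0.24, contralateral 1.48 ± 0.21, healthy-control 1.46 ± 0.22,
hemorrhage 22.1 ± 20.1 mL, edema 24.2 ± 26.2 mL, NIHSS 5.6 ± 5.2 (the
outcome-group-weighted mean), duration 5.3 ± 3.1 days, ALPS–hemorrhage
r = −0.426, ALPS–edema r = −0.592, plus two correlations the summaries do
not pin down and were set to plausible values: hemorrhage–edema 0.70 and
ipsilateral–contralateral ALPS 0.30. The ALPS–ratio correlation (target
−0.489) is **emergent**, not enforced: the relative edema ratio is computed
from the simulated volumes to preserve its definitional identity, so its
correlation is induced by the volume correlations (it comes out weaker,
around −0.4, a known limitation of enforcing the two volume correlations
instead).

Group sizes default to 55 patients (9 subtentorial, the remainder split
left/right at random) and 97 controls, with binary risk-factor prevalences
at the groups' observed proportions. The 90-day outcome (modified Rankin
Scale ≤ 2 = favorable) follows a logistic model on the lesion-side index
(ipsilateral for supratentorial, average for subtentorial): the slope is
ln(1.686)/0.1 per unit ALPS, encoding an odds ratio of 1.686 per 0.1, and
the intercept is calibrated by root finding so the expected favorable
fraction is 39/55 ≈ 0.709, integrating the logistic over the (Gaussian)
linear-predictor distribution. Age and NIHSS coefficients are exposed in
the configuration and default to 0 — whether they entered the true
generating mechanism is unknowable from summaries, so the simulator keeps
the minimal model and leaves them as knobs. The mRS value is then drawn
uniformly within 0–2 or 3–6. Controls carry no lesion fields.

What the simulator does **not** emulate: longitudinal change, missing
data, site/scanner effects, non-Gaussian dependence beyond the copula, any
spatial relation between the imaging phantom and the cohort table. Passing
cohort-level tests therefore demonstrates that the statistics stage
recovers known generating parameters under these idealized conditions, not
that it would behave identically on real registry data.

## Statistics

Two-sided p-values throughout, alpha 0.05, no multiplicity correction.
The two-sample test is pooled Student's t by default (Welch by flag) and
accepts either raw samples or published n/mean/SD summaries, with exact
agreement when the summaries are the raw moments; on the published ALPS
moments (46: 1.34 ± 0.24 vs 97: 1.46 ± 0.22) it gives p ≈ 0.0036,
consistent with the printed 0.003 given input rounding. Normality uses the
Kolmogorov–Smirnov distance with estimated parameters; because the naive
KS null is anticonservative in that case, the p-value comes from a seeded
Monte-Carlo null (the standardized statistic is parameter-free, so one
null table serves a given n). The 2×2 battery offers uncorrected Pearson
chi-square, Yates, and Fisher exact; the default picks Fisher when any
expected cell is below 5. Linear and logistic fits are delegated to
statsmodels (OLS; Logit maximum likelihood) behind this package's result
types, with Wald CIs, per-unit odds-ratio rescaling
(OR_u = exp(u·beta), tested equivalent to rescaling the predictor), rank
and separation checks (|beta| > 50 is reported as suspected separation —
plain ML is used, no Firth penalization, so separated small samples error
out rather than return inflated estimates). The covariate screen keeps
univariate p < 0.1 candidates plus a configurable always-include list
(age, sex, baseline NIHSS).

## Problem sizes and determinism

The oracle checks run a 64 × 64 × 16 phantom (noiseless exactness to 1e-6;
20 Rician seeds at 2% of S0 within 0.05), tensor round-trips to 1e-10,
t-test size over 10,000 null simulations at the study's group sizes,
Fisher-vs-enumeration over all 2×2 tables with total ≤ 20, cohort mean
recovery at n = 5,000 per group, and odds-ratio recovery over 100–200
replicates at the study size n = 55 — sizes chosen so the full battery
runs in minutes on one CPU while keeping Monte-Carlo error well inside
each tolerance. All randomness flows through explicit integer seeds
(NumPy `default_rng`); identical configuration and seeds reproduce
bit-identical phantoms, cohort tables, and pipeline manifests, and the
pipeline skips stages whose outputs already match their recorded
checksums.

## Known limitations

Single-compartment signal model (no crossing fibers, free-water, or
artifact simulation); binary lesion masks only (no intensity-based
segmentation); native-grid ROI means (no interpolation, matching drawn-ROI
practice but not sub-voxel placement); the cohort copula reproduces first
and second moments and pairwise Pearson structure, not higher-order
dependence; and the outcome model is deliberately minimal (single ALPS
driver by default).
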