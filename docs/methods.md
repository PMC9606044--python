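# Methods

This document states the model and procedures implemented in `ambarpet`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions that
affect results.

## 1. Imaging primitives

**Volumes.** Scans are 3-D arrays with an isotropic-or-not voxel size (mm)
and a space tag; operations assert grid compatibility (voxel-size tolerance
10⁻³ mm). On disk, volumes are float32 NIfTI; in memory, float64.

**Preprocessing.** Each scan is divided by its mean over the cerebellar
atlas regions (error if that reference is empty or non-positive), then
smoothed with an isotropic Gaussian of FWHM 8 mm,
σ = FWHM / (2√(2 ln 2)), reflect boundary handling. An FWHM below half the
smallest voxel dimension is a degenerate kernel: a warning is logged and
the scan passes through unchanged.

## 2. Normative template and defect mapping

The template is the voxel-wise mean and sample SD (ddof = 1) of n ≥ 2
preprocessed control scans; the default cohort uses 48. In-brain SDs
(mean > 0) are floored at 1% of the in-brain mean intensity so that
near-noise-free regions cannot produce unbounded Z-scores; the floor value
is recorded on the template.

A patient scan's Z-map is (scan − mean)/SD, zero outside the brain. A voxel
is a **defect** when z ≤ −2 (boundary inclusive) *and* the grey-matter
correction mask holds (GM probability ≥ 0.5); severity codes 1/2/3
correspond to z ≤ −2, −3, −4. Longitudinal voxel classes between two
visits use Δz = z₁ − z₀ with a ±0.5 Z band: improvement is strict
(Δz > 0.5), worsening inclusive (Δz ≤ −0.5), otherwise maintained. A
voxel changing defect status is classified by the status change; when the
Δz rule and the status rule disagree, the status rule wins and the
conflict is counted. A voxel is *outside* wherever either visit's
correction mask is false (`mask_policy="both"`; "later"/"earlier" exist as
options).

## 3. Regional parameters and tests

For each atlas region (restricted to the correction mask) three parameters
are extracted: **metabolism intensity** (mean normalised uptake),
**defect extension** (percent of in-mask region voxels that are defect),
and **defect intensity** (mean Z over the region's defect voxels). Empty
regions yield NaN, never a silent zero. Longitudinal change per region is a
paired t-test over subjects (≥ 3 pairs; all-zero differences give p = 1);
cross-sectional group differences use one-way ANOVA. Tables report counts
of regions with raw p < 0.05 and the percentage rounded to one decimal
(`round(100·n/total, 1)`).

## 4. Voxel-wise statistics and MaskAD

The group contrast is a voxel-wise paired t-test between two visits,
one-sided in the decline direction; zero-variance voxels get t = 0, p = 1.
Suprathreshold voxels (p < 0.001 uncorrected) are intersected with the
in-brain mask (atlas labels > 0) *before* connected-component labelling —
smoothing carries real signal into the off-brain shell, which must not
enter group statistics. Components of fewer than k = 50 voxels under
18-connectivity are discarded. **MaskAD** is the union of surviving
clusters of the placebo arm's baseline→final decline contrast; an empty
mask is reported with a warning and makes downstream percent loss an
explicit error. Each arm's outcome is the mean over subjects of
100 × (mean₁ − mean₀)/mean₀ of in-mask uptake.

## 5. Volumetry

Fifteen subcortical entries (bilateral thalamus, putamen, caudate,
pallidum, hippocampus, amygdala, accumbens, plus brainstem/4th ventricle)
and the GM/WM/CSF tissue classes are carried per subject and visit. Total
intracranial volume is always derived as GM + WM + CSF, never stored.
Structure change uses paired t-tests at α = 0.05; tables report the count
and percentage of significant structures per arm.

## 6. Synthetic generator

**Phantom.** The default grid is 40×48×40 at 4 mm — small enough that the
whole chain runs in seconds, large enough that an 8 mm kernel (σ = 0.85
voxels) and k = 50 clusters behave realistically. The brain is an ellipsoid
(semi-axes 0.44 of the grid), parcellated into 24 Voronoi regions
(provably connected); two inferior regions are cerebellum, four posterior
regions carry the disease signal. GM probability falls quadratically from
0.92 at the centre to 0.50 at the surface, so an atrophy multiplier
strictly shrinks the ≥ 0.5 mask.

**Cohort.** Four arms with study-span (14-month) metabolic declines in the
disease regions — placebo 6.0%, low-albumin 4.5%, low-albumin + IVIG 5.0%,
high-albumin + IVIG 2.0% — two severity strata (mild: multiplier 1.0,
baseline defect offset 10%; moderate: 1.6 and 16%), visits at months
0/2/6/9/14 with linear progression, additive Gaussian scan noise of SD 5 on
uptake ≈ 100, and GM atrophy of 8% per study span. Volumetry declines
annually by 4% (hippocampus), 3% (amygdala, accumbens), 1% (other
structures, GM, WM) with CSF growing 2%, plus measurement noise of 2% of
baseline volume (typical scan-rescan variability of segmentation-derived
volumes).

**What is not emulated.** No spatial registration error, no scanner
harmonisation effects, no partial-volume modelling beyond the smoothing
kernel, no dropout or missing visits, and noise is voxel-wise i.i.d.
rather than spatially correlated at acquisition. The generator is built to
validate the statistics of the chain, not to be photorealistic.

## 7. Self-diagnostics (`ambarpet.experiments`)

- **Type-I calibration** uses *unsmoothed* i.i.d. noise scans, so every
  voxel is an exact null and the binomial reference for the suprathreshold
  rate at p < 0.001 is exact. The smoothed chain is exercised separately.
- **Null MaskAD specificity** pushes a no-signal arm through the full
  normalise → smooth → paired t → cluster chain and counts how often the
  mask stays empty.
- **Recovery** regenerates four-arm cohorts (single stratum, multiplier 1,
  no atrophy, so the seeded decline is the in-mask truth), builds MaskAD
  from placebo, and compares each arm's mean percent loss to the seeded
  value; it also checks the extreme-arm ordering and that MaskAD lies
  inside the seeded signal support. The support is the disease regions
  dilated by 3 voxels: after 8 mm smoothing the true signal genuinely
  extends one kernel halo beyond the seeded labels, so raw-region overlap
  would mislabel real signal as mislocalisation.
- **Regional power/size** seeds decline in the disease regions only and
  counts false positives over *clean* regions — those entirely more than 3
  voxels from the seeded regions — because immediate neighbours are
  genuine (diluted) carriers of the smoothed effect.
- **Volumetry power** seeds a hippocampus-only 3% study-span loss and
  checks bilateral detection with false positives near α elsewhere.

## 8. Reproducibility

All randomness in the pipeline, the generator and the experiments derives
from explicit integer seeds; nested streams use `numpy.random.SeedSequence`
with fixed tags (values kept below 2³¹). `RunConfig` hashes its parameters,
and every CSV a run writes carries `# config_hash=… seed=…` in its first
line, so outputs are traceable to the exact operating point that produced
them.

## 9. Limitations

Cluster-extent thresholding at an uncorrected voxel p is a
sensitivity-oriented choice; no family-wise correction is applied at the
voxel level, and regional tables likewise report raw p < 0.05 counts (a
Benjamini–Hochberg flag is available but not the default). MaskAD is
defined on the placebo arm of the same dataset it summarises, which is a
circularity inherited by design; the recovery experiments quantify the
bias it introduces (measured losses shrink slightly toward zero relative
to the seeded values, since the mask includes halo voxels with diluted
signal). Percent-of-regions figures depend on the parcellation
granularity, which is a free parameter of the phantom.
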