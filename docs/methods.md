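# Methods

`roitex` implements a per-region texture and volumetry pipeline for labeled 3D
brain volumes, together with the group statistics used to compare diagnostic
strata, and a synthetic phantom generator that makes the whole chain testable
without imaging data. This note records the models, the parameters that
matter, the numerical conventions, and the design choices that were genuinely
open.

## The measurement chain

The pipeline consumes a skull-stripped, bias-corrected T1-like intensity
volume at 1 mm isotropic resolution plus an integer parcellation of the same
grid that includes a lateral-ventricle CSF compartment. For every region of
interest (ROI) it produces a volume and three grey-level co-occurrence matrix
(GLCM) texture features.

**Volumetry.** ROI volume is voxel count times voxel volume, reported in cc.
Total brain volume (TBV) is the sum over all segmented structures (including
ventricular CSF), and TBV-normalized fractions are written for reference. The
group tests use raw cc volumes with TBV as a covariate, not the normalized
fractions, so normalization and adjustment are never applied twice. An
intensity-sum volume variant exists as a config switch for sensitivity
analyses; count-based volumetry is the default because the tabulated cc
values require it.

**Intensity chain (per ROI, in order).**

1. *Partial-volume trimming.* Keep voxels with μ − 3σ ≤ v ≤ μ + 3σ, where μ
   and σ are the mean and population SD (divide by n) of the ROI's own
   voxels. Bounds are inclusive so the σ = 0 case is well defined (everything
   retained). By Chebyshev's inequality at 3σ this can never discard more
   than 1/9 of a sample. The trim statistics are per-ROI by default; a
   whole-volume scope can be supplied for sensitivity checks
   (`trim_scope_values`).
2. *CSF-referenced normalization.* Divide by the subject's mean intensity
   over the lateral-ventricle labels. This removes the arbitrary scanner
   scale; a non-positive CSF mean is an error because the division would be
   meaningless.
3. *Quantization.* Linear min–max binning of the retained, normalized values
   into L = 32 grey levels, 1-based: level(v) = min(L, ⌊(v − vmin)/(vmax −
   vmin)·L⌋ + 1), with the degenerate vmax = vmin case mapping everything to
   level 1. Bin edges are per-ROI over retained voxels — the dominant
   fixed-bin-number convention in radiomics — which makes the whole chain
   invariant to any positive affine transform of the raw intensities.
   Excluded voxels carry a 0 sentinel and never enter co-occurrence counts.

**GLCM.** Co-occurrences are counted at voxel distance 1 over the 13 unique
offsets of the 26-neighbourhood (one of each ± pair; the canonical offset is
the one whose first nonzero component is positive). Each ordered pair with
both voxels retained is accumulated symmetrically (C[i,j] and C[j,i]), so 13
directions suffice to cover all 26 neighbours. Each direction's matrix is
normalized to sum 1 *before* averaging, weighting directions equally even
though pair counts differ at mask boundaries; directions with zero valid
pairs are skipped rather than averaged as zero matrices. The averaged matrix
is renormalized (tolerance 1e−6 on input validation) and yields

- contrast = Σᵢⱼ (i−j)² P ᵢⱼ ∈ [0, (N−1)²],
- entropy = −Σᵢⱼ Pᵢⱼ ln Pᵢⱼ in nats (0·ln 0 := 0) — natural log is stated
  explicitly because entropy conventions vary,
- autocorrelation = Σᵢⱼ i·j·Pᵢⱼ ∈ [1, N²].

An ROI with no adjacent retained pair yields a flagged record (NaN features,
zero directions used), never a silent zero.

**Lobe rows.** Lobe volumes are exact sums of member-ROI volumes. Lobe
textures run the full chain once on the *merged* member mask, so trimming and
quantization see the lobe as one region; averaging member features instead is
available as a config switch. With constant but different member intensities,
merged-mask contrast is driven entirely by boundary voxel pairs, which the
tests verify against brute-force enumeration.

## Group statistics

Each ROI (and lobe row) is tested with an ANCOVA: ordinary least squares of
the outcome on treatment-coded group dummies plus covariates — age, sex
(female = 1), years of education, and TBV for volume outcomes or the same
ROI's volume for texture outcomes. The omnibus group effect is a Wald partial
F on the dummy coefficients, identical to a Type III factor test (and to Type
II, since there is a single factor; the suite asserts the zero-covariate case
collapses to classical one-way ANOVA at 1e−10). Effect size is partial eta
squared, η²ₚ = F·df₁/(F·df₁ + df₂), with df₂ = n − k − c for k groups and c
covariates.

Post hoc comparisons contrast covariate-adjusted (estimated-marginal) means
using the pooled model error variance, with Bonferroni adjustment
p_adj = min(1, 3·p_raw). Whether the original post hoc tests compared raw or
adjusted means is not derivable from the outputs alone; adjusted means are
the default here (and the EMMEANS-style convention), with raw-mean t tests
possible by fitting without covariates. Pattern strings follow the tables'
notation: ">" or "<" joins significantly different groups, "," joins groups
whose pairwise test is non-significant, the string is empty when the omnibus
p ≥ 0.05, and it is rendered so the first group letter leads ("a < b, c"
rather than "b, c > a"). No correction is applied across ROIs beyond the
within-ROI Bonferroni, mirroring the source analysis; a global FDR pass is
deliberately out of scope for the default tables.

Demographics use one-way ANOVA for continuous variables and Pearson
chi-square without continuity correction for sex. Inter-rater agreement uses
ICC(2,1) — two-way random effects, absolute agreement, single measure — via
pingouin, with an F-based 95% CI; the form is a documented choice since
rating protocols rarely name one, and the suite cross-checks it against the
hand mean-squares formula.

## The phantom cohort generator

The phantom emulates exactly the inputs the pipeline consumes: a labeled
volume per subject, an intensity volume per subject, and a demographics
table. It is deliberately geometric, not anatomical.

**Geometry.** Each ROI is a near-cubic cuboid placed on a non-overlapping 3D
grid with background gaps; the achieved voxel count after cuboid rounding is
stored back on the region recipe. Exact voxel accounting is the point: volume tests
can then assert to ±1 voxel. The default parcellation carries the full
grey-matter inventory at the published reference-group magnitudes (e.g.
hippocampus 7.2 cc), a white-matter filler and a 30 cc ventricular CSF
compartment, summing to ≈985.5 cc of TBV.

**Intensity model.** A region with base mean m generates

    v = m + σ_smooth · S + σ_tex · mult · T + σ_noise · E

where S is a unit-variance Gaussian field smoothed to `smooth_fwhm_vox` and
centred within the ROI (fixed anatomical low-frequency variation), T and E
are i.i.d. standard normal fields, and `mult` is the group's texture
multiplier for that region. The choice to make the *disease* dial a
voxel-scale (unsmoothed) field is deliberate: because quantization is per-ROI
min–max, GLCM contrast measures the *share* of voxel-to-voxel variance in the
total, so only a fine-scale dial maps monotonically (and increasing) onto
contrast — matching the reading of texture contrast as microstructural
heterogeneity. Scaling a smoothed field instead would *lower* normalized
contrast, because it raises the spatially correlated share. The monotonicity
is verified over 20 paired-seed replicates. Defaults (grey matter):
σ_smooth = σ_tex = 12–15, FWHM 3 voxels, σ_noise = 8 on a base of 400
(CSF 100, white matter 620) — chosen to give mid-range baseline contrast
(≈20–45 of the 961 maximum) with realistic relative noise.

**Atrophy.** Group atrophy removes a fraction f of an ROI's voxels by
boundary erosion: whole 6-neighbourhood erosion shells are peeled while they
fit, and the final partial shell is removed farthest-first by geodesic (BFS)
distance from a deepest-interior root voxel with a seeded random tie-break.
Removing voxels in strictly decreasing geodesic-distance order can never
disconnect the remainder (every retained voxel's shortest path to the root
passes only through nearer voxels), so the ROI stays 6-connected and the
rounded target count is hit exactly. Per subject, each grey-matter ROI's
fraction is jittered as clip(f_group + N(0, 0.10), 0, 0.9): the 0.10 SD
reproduces the ~10–16% coefficient of variation of regional grey-matter
volumes in elderly cohorts and gives the volume ANCOVA a non-degenerate,
realistically dispersed outcome. Without between-subject volume variability
the eroded volumes would be identical within a group and the regional-volume
covariate of the texture ANCOVA would be collinear with the group dummies.

**Demographics.** Age and education are truncated-normal draws (age ≥ 60,
education ≥ 0) at the published per-group means and SDs; sex is
Bernoulli(female proportion); MMSE is generated for table reproduction only
and never used by the statistics.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: anatomical ROI shapes and adjacency, bias fields,
motion, Rician noise, partial-volume mixing at tissue interfaces, hemispheric
structure, and any real coupling between pathology load and texture units.
Real-data effect magnitudes are not derivable from published summary tables;
the phantom's multipliers are free parameters used to exercise calibration
and power, not estimates.

## Simulation studies and sizes

Two designed experiments back the statistical claims, both on a miniature
5-region parcellation (ROIs of 512–729 voxels plus CSF) so that hundreds of
cohorts run in minutes; it is the statistical structure, not anatomical
scale, that these studies exercise.

- *Null calibration*: 500 cohorts of n = 20/20/20 with all multipliers 1 and
  atrophy 0. Pooled over four grey-matter ROIs and both analysis kinds (4000
  tests), the omnibus rejection rate must sit inside the 95% binomial
  interval around α = 0.05, and non-empty post hoc patterns may not exceed
  that band (a typical run gives ≈0.049 and ≈0.040).
- *Dissociation recovery*: 100 replicates of n = 40/40/40 in which the target
  region receives texture multipliers (1, 1.6, 2.0) across the three strata
  but atrophy (0, 0, 0.15) only at the MCI stage. A replicate is recovered
  when texture is significant for both neurodegeneration-positive groups
  while volume separates only the MCI group (Bonferroni-adjusted p < 0.05).
  The multipliers were sized from a pilot of the contrast mean/SD response to
  give well above 80% power at this n.

## Numerical conventions and degenerate inputs

- Population SD (÷n) everywhere the trim window is computed; fixed so tests
  are exact.
- GLCM normalization tolerance 1e−6 on feature input; averaged matrices are
  renormalized to absorb float drift (sum within 1e−9 thereafter).
- Degenerate cases: σ = 0 trims nothing; vmax = vmin quantizes to level 1;
  constant ROIs give contrast 0, entropy 0, autocorrelation g²; an absent
  label yields a flagged zero-volume record; an ROI without any adjacent
  retained pair yields a flagged NaN feature row, which the table builder
  skips explicitly.
- Reproducibility: every stochastic step derives its stream from
  (seed, label or subject index) so a region's realization is independent of
  which other regions exist; fixed seeds give byte-identical cohorts,
  feature CSVs and tables.

## Known limitations

Cuboid ROIs understate boundary effects of convoluted cortical shapes;
distance-1, 32-level GLCMs are the only texture configuration implemented
(multi-distance and other Haralick features are out of scope); lobe rows pool
regions as unilateral blocks rather than hemisphere pairs; and the ANCOVA
assumes the usual linear-model conditions — with strongly non-normal outcomes
the printed p-values inherit the F test's (good, but not exact) robustness.
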