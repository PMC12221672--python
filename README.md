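# roitex

Per-ROI 3D grey-level co-occurrence (GLCM) texture, TBV-normalized
volumetry, and ANCOVA group statistics for labeled brain volumes — plus a
synthetic phantom cohort generator that makes the entire chain testable end
to end without any imaging data.

## The problem

In suspected non-Alzheimer disease pathophysiology (SNAP) and related
neurodegenerative conditions, microstructural tissue changes can precede
measurable atrophy: the texture of a region's T1 signal becomes more
heterogeneous before its volume shrinks. Detecting that requires (a) a
texture measure that is comparable across subjects and scanners, (b)
volumetry that controls for head size, and (c) group statistics that adjust
for demographic covariates. `roitex` packages that workflow for researchers
who have a parcellated T1-like volume per subject (e.g. from FreeSurfer) and
a subject table with diagnostic group, age, sex and education.

## The method

For each ROI, intensities are trimmed to [μ − 3σ, μ + 3σ] (partial-volume
control), divided by the subject's mean lateral-ventricle CSF intensity, and
re-quantized to N = 32 grey levels by per-ROI min–max binning. Symmetric
co-occurrence matrices are built at voxel distance d = 1 over the 13 unique
directions of the 26-neighbourhood, normalized per direction, and averaged.
Features on the averaged matrix P:

```
contrast        = Σᵢ Σⱼ (i − j)² P(i,j)          (local grey-level variation)
entropy         = −Σᵢ Σⱼ P(i,j) ln P(i,j)        (co-occurrence disorder, nats)
autocorrelation = Σᵢ Σⱼ i · j · P(i,j)
```

Volumes are voxel count × voxel volume in cc, with total brain volume (TBV)
the sum over all segmented structures. Each ROI is then tested with an
ANCOVA — `y ~ group + age + sex + education + TBV` for volumes, the same
with the ROI's own volume replacing TBV for textures — using a Type III
partial F for the group effect, partial eta squared
η²ₚ = F·df₁/(F·df₁ + df₂) as effect size, and Bonferroni-corrected pairwise
contrasts of covariate-adjusted means rendered as table-style pattern
strings ("a < b, c" etc.). Demographics get one-way ANOVA / chi-square, and
two-rater agreement gets ICC(2,1). See `docs/methods.md` for the full
conventions.

The phantom module generates cohorts of cuboid-parcellated label volumes
with a CSF compartment, a controllable voxel-scale heterogeneity dial that
maps monotonically onto GLCM contrast, connectivity-preserving boundary
erosion as the atrophy dial, and demographics drawn from published group
distributions — so calibration, power and accounting properties of the whole
pipeline are verifiable to the voxel.

## Worked example

Simulate a three-group cohort (n = 40/40/40) in which the entorhinal region
receives a texture effect at *both* neurodegeneration-positive stages but
atrophy only at the MCI stage, then run the full analysis:

```python
from roitex import generate_cohort
from roitex.pipeline import extract_cohort_features, run_analyze
from roitex.studies import dissociation_cohort_spec

spec = dissociation_cohort_spec(n_per_group=(40, 40, 40), seed=7)
cohort = generate_cohort(spec)
features = extract_cohort_features(cohort)
tables = run_analyze(features, cohort.subjects)

cols = ["roi", "mean_sd_a", "mean_sd_b", "mean_sd_c",
        "F", "p", "partial_eta_sq", "pattern"]
print(tables["table2_volume"].query("roi == 'entorhinal'")[cols].to_string(index=False))
print(tables["table3_texture"].query("roi == 'entorhinal'")[cols].to_string(index=False))
```

which prints (a = N-CN, b = N+CN, c = N+MCI):

```
       roi     mean_sd_a     mean_sd_b     mean_sd_c        F        p  partial_eta_sq  pattern
entorhinal 0.490 (0.035) 0.488 (0.030) 0.451 (0.042) 8.959286 0.000245        0.136868 a, b > c

       roi  mean_sd_a  mean_sd_b  mean_sd_c         F            p  partial_eta_sq   pattern
entorhinal 47.7 (4.8) 54.8 (4.9) 59.1 (5.5) 35.285792 1.241434e-12        0.384436 a < b < c
```

Read the patterns: texture contrast rises stage by stage ("a < b < c" — both
N+ groups differ from the reference), while volume separates only the MCI
group ("a, b > c"). That is the texture-before-volume dissociation the
pipeline is designed to expose. `run_analyze` also writes `table1.csv`
(demographics with ANOVA/chi-square p-values), `table2_volume.csv`,
`table3_texture.csv`, a long-format `stats.csv` with raw and adjusted post
hoc p-values, and a JSON run manifest when given an output directory.

The same workflow is available from the shell:

```bash
roitex simulate --n-per-group 10,10,10 --seed 7 --out cohort/
roitex extract --subjects cohort/subjects.csv --images cohort/ \
               --roi-map cohort/roi_map.csv --out features.csv
roitex analyze --features features.csv --subjects cohort/subjects.csv --out tables/
roitex full --seed 7 --out run/          # all three in one reproducible run
```

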