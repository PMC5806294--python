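# Methods

## Statistical model

The analysis is mass-univariate ordinary least squares.  Per-group SCN
maps regress each in-mask voxel's GM value on the extracted seed volume
plus nuisance covariates and test the seed coefficient one-sided
(positive covariance).  The genotype × seed interaction is a single
pooled model over both strata with seed, group (AA = 1), their product
and the covariates; the product coefficient is the difference in
covariance slopes and is tested one-sided in either direction.  Using a
pooled model with a common residual variance is the standard
slope-difference (heterogeneity-of-slopes) test; fitting the two groups
separately and differencing the slopes gives the same point estimate but
a different variance estimate, and the pooled form is what the
interaction cluster tables and the AA−G covariance-strength difference
CI are based on.  The direct VBM group comparison is the same engine
with a two-sided test on the group indicator.

t statistics use `t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)` with `dof = n − rank(X)`.
The vectorized implementation factors `(X'X)⁻¹X'` once per design and is
algebraically identical to solving the normal equations voxel by voxel
(verified against an explicit per-voxel oracle to ~1e-12 relative).

Numerical conventions:

- Nuisance covariates (age, MMSE, TIV) are mean-centered before fitting;
  this does not change the seed or interaction t statistics.
- Voxels whose values do not vary across subjects are degenerate; they
  are flagged and assigned t = 0, p = 1 rather than dividing 0/0.
- Rank-deficient designs are rejected with the collinear columns named
  (identified from near-null singular directions).

## Inference on maps

P maps are thresholded with Benjamini–Hochberg at q = 0.05 over the
in-mask voxels of each contrast map independently — no pooling across
seeds, strata or directions.  Suprathreshold voxels are partitioned into
connected components under 18-connectivity by default (6 and 26 are
selectable); component labels are renumbered by the lexicographically
first voxel so labeling is deterministic regardless of the underlying
library's scan order.  The extent filter is strictly greater-than: a
100-voxel threshold removes a cluster of exactly 100 voxels.  Cluster
peaks are the within-cluster argmax of t, ties broken by lexicographic
voxel order; secondary peaks ("s.c." rows) are accepted greedily in
descending t provided they lie at least 8 mm (world distance) from every
previously accepted peak — the 8 mm separation is a package default, as
is the cap of 8 sub-peaks per cluster.  Anatomical labels are not
bundled; a user-supplied label volume can name regions.

## Seed ROIs

A sphere mask includes a voxel iff its centre lies within the radius of
the seed centre (closed ball); the voxel nearest the centre is always
included so masks are never empty.  Seed volume is by default the sum of
voxel values times the voxel volume (mm³) — the natural reading of a
modulated GM map, where voxel values are volume densities.  A mean
aggregation (per-voxel GM density) is also available and is what the
parameter-recovery checks use, because it puts the extracted regressor
in the same units as the generator's latent variable.  Whether a study
sums or averages inside the sphere is rarely decisive: the two differ by
a constant factor on a fixed grid, leaving t statistics unchanged.

## Synthetic cohorts

The generator emulates a two-stratum early-Alzheimer's cohort: 76
G-allele carriers and 28 A homozygotes of a functional SNP, with
per-stratum covariate moments (age 73.4 ± 7.6 vs 71.8 ± 7.4 years,
MMSE 21.6 ± 5.7 vs 20.6 ± 5.1, education 5.7 ± 5.4 vs 5.4 ± 5.1 years,
male fractions 42/76 and 11/28) and a synthetic TIV
(1.4 × 10⁶ ± 1.3 × 10⁵ mm³) drawn independently of the latent.  Age and
education are truncated at 0 and MMSE clipped to 0–30.  Within the
carrier stratum, GG/GA genotypes are split at the Hardy–Weinberg
proportion implied by the AA fraction of the cohort, so the simulated
genotype distribution is close to equilibrium by construction.

Images live on a 32 × 38 × 32 grid of 3-mm isotropic voxels with a
centered origin — a deliberately small MNI-like space that still
contains all four catalog seed coordinates and exercises the
world↔voxel affine math.  Each subject carries a latent scalar
(Normal(0.5, 0.1)) standing for seed-region integrity.  Voxels inside
the 4-mm seed sphere are set to that latent, so sphere extraction is the
measurement channel (the regressor is measured with the same voxel noise
as everything else).  Each planted spherical cluster adds
`b0 + b_g · latent + Σ loading_c · covariate_c` to its voxels, where the
slope `b_g` depends on the genotype stratum: the default configuration
plants one interaction cluster (slopes 0.5 vs 1.5, with small age and
TIV loadings so nuisance adjustment is genuinely exercised) and one
equal-slope cluster (a valid null for the interaction).  Independent
Gaussian noise (SD 0.05) is added, optional Gaussian smoothing applied,
and values clipped at 0 (GM density is nonnegative).  Behaviour scores
are linear in the mean GM of a designated cluster plus noise; NPI items
are per-stratum truncated-Poisson draws whose rates were chosen to land
near group totals of ≈7.5 (G) vs ≈3.4 (AA) — the item-level
distributions are free parameters, not calibrated claims, since only
totals are commonly reported.

What the simulator does *not* emulate: spatial autocorrelation of
anatomy, registration error, partial-volume effects, non-Gaussian
residuals, site effects, or realistic covariance between distant regions
beyond the planted clusters.  Passing tests therefore demonstrate that
the estimators and the inference chain are correct and calibrated under
the stated generative model, not that the pipeline is robust to every
property of real MRI data.

## Calibration and recovery checks

- **Null calibration.**  With equal slopes in both strata, the
  interaction-map p-values over ≥10,000 analysis voxels (n = 104) pass a
  Kolmogorov–Smirnov uniformity test, and BH at q = 0.05 plus the
  >100-voxel extent filter yields zero clusters in essentially all
  replicates.  The analysis mask for this check excludes the seed sphere
  itself, whose voxels encode the regressor and are not null by
  construction.
- **Recovery.**  With the default planted slope difference of 1.0 and
  noise SD 0.05, the detected cluster overlaps the planted sphere at
  Dice ≈ 1 and the interaction coefficient — summarized as the mean over
  detected-cluster voxels, in latent units via mean-aggregated seed
  extraction — recovers ≈0.97–0.99.  The small systematic shortfall is
  classical regression-dilution: the extracted seed carries voxel noise
  (attenuation factor ≈ σ²_latent / (σ²_latent + σ²_noise/m) for an
  m-voxel sphere, ≈0.98 at the defaults), well inside two standard
  errors.
- **CI coverage.**  The per-group 95% covariance-strength CIs (t-based,
  group residual dof) cover the generating slope at the nominal rate
  (95.2% over 4,000 simulated fits).

Problem sizes in the test suite and the acceptance script (grid
dimensions, replicate counts of 20–500, 50 GLM oracle instances) were
chosen to keep a full desk run in the low minutes while leaving the
stochastic checks comfortable statistical margins.

## Pipeline conventions

The default analysis mask is "mean GM across subjects > 0.1", a common
VBM heuristic, overridable by an explicit mask file.  TIV is taken from
the phenotype table when present and otherwise integrated from each
subject's image.  The two-group (G vs AA) analysis is primary; a
three-genotype mode (GG/GA/AA) runs the per-stratum SCN maps only, for
qualitative comparison.  Negative-covariance (anticorrelation) contrasts
and family-wise-error/random-field cluster inference are out of scope.
Every run writes a JSON manifest (config snapshot, stage timings, output
inventory, input checksums in file mode) even when a stage fails.

## Known limitations

- FDR is voxel-level BH; the extent filter is descriptive, not a
  cluster-level p-value.
- The adjusted Spearman correlation is a partial correlation on average
  ranks with a t approximation (n − 2 − k dof); confounders default to
  age + education and are configurable.
- The Mann–Whitney exact path requires tie-free samples with n ≤ 12 per
  group; otherwise the tie- and continuity-corrected normal
  approximation is used.
- Covariance-strength CIs assume Gaussian residuals within group; no
  robust/bootstrap variant is provided.
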