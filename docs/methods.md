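# Methods

This note documents the statistical procedures implemented in `lesionmap`,
the synthetic data-generating process used to validate them, the numerical
choices that matter, and the limits of what the validation shows.

## Coordinate conventions

All volumes live on a `GridSpec`: a regular 3D grid with a diagonal
voxel-to-world affine (no rotation). The default grid is 32³ voxels at 2 mm
— a desk-scale stand-in for a standard space; all reported coordinates are
world mm via the affine, so the analysis code is grid-agnostic. World x = 0
is the midline; x < 0 is the left hemisphere (neurological convention).
Axial slices are indexed along the third voxel axis. Voxel indices are
0-based internally; every external report (cluster tables) uses world mm.

## CST impairment percentage

For a lesion L and fiber subset F (binary volumes on the common grid), each
axial slice z with |L ∩ F|_z > 0 contributes the ratio
100·|L ∩ F|_z / |F|_z, and the impairment percentage is the maximum over
such slices, together with the argmax slice. The denominator is the
subset's area *in the same slice*, the convention used for slice-wise CST
lesion-load scores; a whole-volume ratio is available via
`method="volume"`. Area is counted in voxels; with isotropic in-plane
resolution this equals mm² up to a constant that cancels in the ratio.
Edge behaviour: no overlapping slice → (0, None); lesion ⊇ subset → 100.

## Mass-univariate group mapping and cluster correction

Cortical maps are modelled as 2D "measure sheets" (default 64×64 at 2 mm),
one per subject and measure. At every point, OLS regresses the measure on a
group indicator plus nuisance covariates (age, sex, scanner dummies, and
the subject's global value of the matched measure); the group coefficient's
two-sided t is reported. Familywise error across points is controlled by
cluster-extent Monte Carlo: suprathreshold clusters (voxel p < .01,
sign-specific, 4-connected) are referred to the null distribution of the
maximum cluster extent in Gaussian noise fields smoothed to the analysis
FWHM (10 mm default), with cluster p = (1 + #{sims ≥ observed}) / (n_sims + 1)
— the add-one estimator avoids zero p-values. Two numerical points matter:

- **Null fields are thresholded at their own Gaussian quantile** matching
  the two-sided voxel p, not at the t quantile of the analysis degrees of
  freedom. The simulated fields are Gaussian; pushing them through the
  t quantile would give them a smaller pointwise suprathreshold rate than
  the observed t map and undersize the null clusters (measured FWER 0.16
  instead of ~0.05 in a 200-cohort null study).
- **Unit variance is enforced deterministically**: simulated fields are
  generated on a padded domain, cropped, and divided by the L2 norm of the
  smoothing kernel. Dividing by a field's realized standard deviation
  couples all its points and distorts the extent distribution; the padded
  crop keeps the field stationary up to the boundary. The same generator is
  used for synthetic subject sheets. With both choices the measured
  familywise error on null cohorts is 0.02–0.05 across seeds at nominal .05.

ROIs are defined by discovery → replication: clusters surviving the
Monte-Carlo correction in the discovery sample are seed masks; the GLM is
refit on an independent replication sample restricted to each mask, and
points with p < .05 and the discovery sign form the confirmed ROI.

## ROI-level inference

- **ANCOVA**: one OLS fit of the measure on PR/CR dummies (HC reference)
  plus covariates; pairwise contrasts PR–CR, PR–HC, CR–HC with two-sided t
  tests at the residual degrees of freedom. Cohen's d is computed on
  covariate-adjusted values (residuals + group effects) by default so that
  d and contrast agree in sign and scale; raw-value d via `adjusted_d=False`.
- **Partial correlation**: Pearson correlation of the OLS residuals of both
  variables on the covariates (with intercept); p from t with
  df = n − 2 − k. Categorical covariates are dummy-coded with the
  lexicographically first level as reference.
- **BY-FDR**: step-up with thresholds i·q/(m·c(m)), c(m) = Σ_{j≤m} 1/j;
  corrected p-values are p·m·c(m)/i with monotonicity enforced from the
  largest rank down. BY is used for the correlation and slope families;
  each family's membership is explicit in the calling code, never implicit.
- **CST correlation family**: for each ROI and subset, the partial
  correlation of that subset's impairment with the ROI measure controls for
  age, sex, scanner *and the other three subsets' impairments*; the family
  (#ROIs × 4) is BY-corrected together. Subsets with constant impairment
  are reported as not testable rather than raising.

## VLSM

Outcome = chronic ROI measure; predictor = binary lesion status per voxel;
covariates = age, sex, scanner, lesion volume. Voxels must be damaged in
strictly more than 10 % of patients and have both lesioned and intact
subjects (constant-status voxels are skipped with a warning, as is
mass-univariate convention). The per-voxel t for the lesion coefficient is
computed for all voxels in one vectorized pass via Frisch–Waugh–Lovell
residualization, which is algebraically identical to the full per-voxel
OLS. Voxel p-values are corrected by Benjamini–Hochberg within each map
(BY selectable); surviving voxels form 6-connected clusters and only
clusters with strictly more than 10 voxels are reported, with unweighted
centroid and max-|t| peak in world mm and volumes in mm³.

## Longitudinal mixed model

Per ROI and group, `y_ij = β0 + β1·t_ij + b_i + e_ij` with
b_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_e): a common slope per group and random
intercepts absorbing within-subject correlation; subjects contribute
whatever visits they have (≥ 2 required). REML estimation is profiled to a
1D search over λ = σ²_b/σ²_e on the log scale (bounded Brent, tolerance
1e-10, ≤ 500 iterations); the boundary λ = 0 is always evaluated and kept
when it wins, so σ²_b pins at zero and the fit reduces exactly to OLS.
With exactly-collinear (noiseless) data the fit short-circuits to the exact
solution with zero variances. Slope tests are Wald z; pairwise cross-group
contrasts use (β1_a − β1_b)/√(SE_a² + SE_b²) against the normal reference —
a cross-model contrast has no standard t degrees of freedom, and group
sizes of ≥ 30 make the normal approximation adequate. Slope and
slope-difference families are BY-corrected separately across ROIs. A
pooled interaction-model alternative (`fit_interaction_model`, statsmodels
MixedLM) is provided for comparison.

Evolution patterns are labeled by rules:
1 = both patient slopes negative with significant PR decline;
2 = both positive, both significant; 3 = significant CR increase with PR
not significant; 4 = significant PR–CR difference with reliably opposite
signs. "Reliably" means the raw Wald p of each patient slope is ≤ .05:
an ROI whose only real change is a CR increase can show a significant
PR–CR contrast with a noise-sign PR estimate and is labeled 3, not 4,
while a genuinely divergent ROI stays 4 even when one slope's
family-corrected p slips past the threshold.

## Synthetic data-generating process

The generator emulates the *statistical structure* of a two-sample
subcortical-stroke morphometry study, not its anatomy:

- **Fiber atlas**: four tapering columns per hemisphere (M1/PMC/SMA/S1
  origin) spanning ≥ half the z extent, with per-slice radius variation so
  the slice-wise maximum is non-trivial.
- **Lesions**: ellipsoids clipped to the designated hemisphere, centred
  near a posterior-limb locus (y = 0.58·ny) with jitter, target volumes
  80–400 voxels (0.6–3.2 cm³, typical capsular infarcts; no volume
  distribution is prescribed by the source data, so it is config). The
  fraction of patients whose lesion transects a subset bounds the
  attainable patient-vs-control effect size (d ≤ √(p/(1−p)) for a
  carrier-concentrated deficit), which drove these defaults.
- **WE_FM**: 100 − 0.5·(M1 impairment %) + N(0, 6), truncated to [0, 99];
  the top 45 % of raw scores snap to exactly 100, producing the CR point
  mass and guaranteeing both strata are populated (regeneration with a
  retry cap otherwise fails loudly).
- **Measures**: value = baseline + covariate effects (age, sex, scanner)
  + injected chronic deficits + group slope × months + subject random
  intercept + noise. Deficits are triggered by fiber impairment (graded:
  δ·impairment/100), by stratum (PR/CR, binary), or by lesion coverage of a
  locus voxel (binary, mirror-symmetric). Defaults inject a precentral
  thickness deficit via M1 fibers, a postcentral one via S1 fibers, and a
  PR-only cingulate area deficit, each ~1.5–2 residual SDs at the mean
  triggering impairment. Default slopes realise the four evolution
  patterns; intercept SD equals residual SD (ICC ≈ 0.5) so variance
  components are identifiable at n ≈ 80.
- **Visits**: nominal 0.25/1/3/8 months with ±20 % uniform jitter,
  mirroring fluctuating acquisition times; the chronic stage is the last
  visit. Sheets carry the same chronic deficits as 6×6 patches at fixed
  per-ROI locations over smooth noise.

What this does **not** emulate: vascular lesion shapes, registration error,
surface topology (sheets are flat), site/scanner interactions beyond an
additive offset, measurement floor/ceiling effects, and attrition beyond
random visit dropout. Passing tests therefore demonstrate statistical
correctness and calibration of the pipeline, not robustness to the
real-world artefacts those features create.

## Validation studies and problem sizes

The acceptance suite and `scripts/acceptance.py` run, per seed: exact
oracle equivalence for the impairment statistic (100 random 16³ pairs) and
BY-FDR (1000 random p-vectors vs brute-force step-up); VLSM null
calibration (200 cohorts, n = 60) and lesion-locus localization (50
replicates, two-locus placement, d ≈ 1 carrier deficit — the two-locus
design puts voxel lesion status in register with carrier status, the regime
in which a mass-univariate map at this sample size is informative);
Monte-Carlo FWER (200 null cohorts, 500 simulations each); ANCOVA type-I
error (1000 nulls) and PR-deficit recovery; LMM slope CI coverage (300
balanced cohorts of 40×4) and divergent-pattern classification (20 default
cohorts); and the full default pipeline (80 patients + 40 controls,
discovery and replication). These sizes keep the whole suite to a few
minutes on one CPU while leaving the binomial noise of each rate well
inside its acceptance band. Demo-scale caveat: at n = 80/40 the
patient-vs-control confirmation of the carrier-limited postcentral deficit
is marginal for some seeds; the structural checks use fixed seeds and the
reproduction script reports whatever the given seed produces.

## Known limitations

- Cluster-extent calibration assumes the smoothness of the analysed maps
  matches the nominal FWHM; real data would require estimating FWHM from
  residuals first.
- The impairment statistic is defined for binary atlases only.
- Pairwise LMM contrasts ignore the (zero under independent groups)
  covariance between group fits and use a normal reference; with < ~20
  subjects per group a parametric-bootstrap reference would be preferable.
- BY correction families are fixed by the calling code; there is no
  automatic family discovery.
- The pattern rules are deliberately rigid; borderline ROIs (e.g. a
  CR-only increase with an incidentally significant group contrast) follow
  the documented precedence rather than any probabilistic assignment.
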