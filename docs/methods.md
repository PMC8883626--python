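# Methods

## The biometric twin model

A trait measured on twin pairs is decomposed into additive genetic (A),
common/shared environment (C) and unique environment plus error (E)
variance. A pair's trait vector is bivariate normal with common mean μ,
marginal variance V = σ²_A + σ²_C + σ²_E and covariance

* MZ pairs: σ²_A + σ²_C (identical genomes share A fully),
* DZ pairs: ½σ²_A + σ²_C (additive effects correlate 0.5),

with C contributing equally to both zygosities. `fit_twin_model` maximizes
the exact sum of bivariate-normal log densities. Non-negativity of the
components is enforced by optimizing their square roots (squared inside the
likelihood), which keeps the optimizer unconstrained; a component estimated
at the boundary simply comes back as 0. Nelder–Mead is run from four
moment-informed starts (the Falconer solution plus three spread points) and
the best optimum is kept; on every dataset we have examined this preserves
the nesting relation ll(ACE) ≥ ll(AE), ll(CE), ll(E), which the test suite
asserts. Note the correct AIC corollary of nesting is
AIC(ACE) ≤ AIC(AE) + 2 — the richer model can have a *much lower* AIC when
shared environment is real, never an AIC more than 2 above the nested one.

Standardized proportions h² = σ²_A/V, c², e² are scale-free: they are
invariant to affine transformation of the trait (tested). AIC is
2k − 2·loglik with k counting the mean plus the free components (ACE 4,
AE/CE 3, E 2); the lowest AIC wins and exact ties go to fewer parameters.
Confidence intervals for h² come from a percentile bootstrap over pairs,
resampled within zygosity (default 500 resamples, seeded); the paper-style
two-step approach is used for covariates: traits are OLS-residualized on
age, sex and BMI and re-standardized before pairing, rather than estimating
a mean structure jointly.

The binary breakfast trait is fitted with the same Gaussian likelihood
(coded 0/1 after covariate residualization). This mirrors linear structural
equation modelling of a binary phenotype and is documented as a caveat: a
liability-threshold model would be the more principled choice and is out of
scope; observed-scale h² for a binary trait understates liability-scale h².

## Synthetic twin cohorts

`generate_twin_trait` draws latent A, C, E standard normals scaled by
√a², √c², √e²; MZ co-twins share the A latent, DZ co-twins share half its
variance (a₁ = √½·A_shared + √½·A_unique), both share C. Expected pair
correlations are a² + c² (MZ) and ½a² + c² (DZ), verified at n = 10⁴ pairs.

`generate_cohort` turns traits into observable data:

* **Demographics** — 88% female, age ~ N(58.65, 14.07²) shared within pair,
  BMI ~ N(25.94, 4.98²), sex-specific heights; weight derived from BMI.
* **Eating window** — 8.46 + 2.60·z hours (z the ACE trait with a² = 0.33),
  clipped to a plausible 4.2–15.5 h range.
* **Breakfast status** — an a² = 0.11 liability thresholded at 88%
  prevalence; consumers start eating at ~07:45, skippers after 11:00.
* **Menus** — breakfast/lunch/snack/dinner occasions drawn from a bundled
  ~50-item catalogue with realistic co-draws (tea with semi-skimmed milk,
  tomato–lettuce salads), then all nutrients scaled so record energy matches
  the participant's latent energy target, N(1847.42, 550.18²) kcal with ACE
  structure (a² = 0.13, c² = 0.10). First and last occasions pin the eating
  window exactly.
* **FFQs** — per-nutrient normal-scores mixtures ρ·z_EFR + √(1−ρ²)·noise
  (default ρ = 0.40), giving Spearman correlations in the weak-to-moderate
  range typical of acute-vs-habitual instrument comparisons; ~5% of FFQs get
  a high incomplete-item count so the exclusion rule has work to do.
* **Completeness** — per record and field, a state (complete / incomplete /
  missing) is drawn with configurable probabilities (defaults 0.55/0.45/0
  for portions, 0.84/0.16/0 descriptions, 0.97/0.03/0 timings, matching the
  reported record-level completeness mix); "incomplete" records mix complete
  and degraded entries. The resulting mean quality score is ≈ 5.4.

What the generator does **not** emulate: the real 4957-item food universe
and its coding idiosyncrasies, correlated missingness across fields, seasonal
or weekday menu structure, energy misreporting correlated with BMI, and
opposite-sex-specific DZ effects. Passing tests therefore demonstrate that
the *methods* are implemented correctly and recover known generating
parameters — not that real-cohort estimates would take any particular value.

## Quality scoring and exclusions

Field completeness is judged structurally, since dietitian judgement cannot
be replicated deterministically: a portion is complete only if it carries a
quantity token (digit or measure word), a time only if it parses as 24-h
"HH:MM" or 12-h "H:MM am/pm" (unparseable times count as incomplete for
scoring and as missing for time-based analyses), a description only if it is
more than one truncated word. Component scores are 2 if all entries
complete, 0 if the field is absent everywhere, else 1.

The exclusion cascade labels each record with its *first* failing rule, and
±2 SD bands are recomputed per batch on the records surviving earlier rules
(configurable; a report's thresholds can be frozen and reapplied, making the
cascade idempotent on its kept set). The BMR/energy ratio is computed as
BMR ÷ energy — the direction is not standardized in the literature and the
two are not equivalent under a symmetric SD rule, so it is a documented
switch-able default. The original 1919 Harris–Benedict coefficients are
used, kept in one constant table.

Food-key aggregation resolves variant descriptions of one item: the variant
with the most complete nutrient vector wins; equally complete variants are
averaged nutrient-wise only where values differ by ≤ 5% of their mean, and
disagreements are flagged for manual review instead of silently merged.

## Energy adjustment, concordance, networks

Nutrients are energy-adjusted by the Willett residual method per batch:
residual from the OLS line of nutrient on energy, plus the fitted value at
the batch mean energy. This preserves batch means exactly and zeroes the
within-batch energy slope (both asserted to numerical tolerance); the
adjustment is idempotent.

For concordance, each participant keeps the EFR–FFQ pair with the smallest
date gap (ties to the earliest EFR). Spearman ρ uses the tie-corrected rank
correlation with pairwise-complete observations. The Procrustes test
z-scores nutrients, embeds Euclidean distances by classical PCoA (all
positive-eigenvalue axes retained by default — Euclidean input guarantees
none are negative), centers and scales both configurations to unit sum of
squares, and takes m² = 1 − (Σ singular values)² from the SVD of Y′X — the
standard protest formulation; the null permutes rows of Y and the add-one
rule keeps p ≥ 1/(n_perm + 1). Narrower configurations are zero-padded so
differently sized embeddings remain comparable.

Co-occurrence networks de-duplicate items within each one-day record and
count unordered pairs across records. The all-day variant removes staple
beverages (milk, coffee, tea, wine — a bundled, editable id list) which
would otherwise dominate every edge; the breakfast variant keeps only
entries timed strictly inside (06:00, 11:00) and retains beverages.
De-duplication is per record: each record is one participant-day, and the
few participants with multiple records contribute each record separately.

## Mixed-effect associations

Behaviour–outcome associations use Gaussian linear mixed models with
*crossed* random intercepts for family and zygosity, fitted by maximum
likelihood (not REML) so the behaviour term can be tested against the null
model by a likelihood-ratio chi-square. Zygosity has only two levels, which
makes its variance component weakly identified and the likelihood surface
flat along one direction; the fitter therefore runs BFGS and L-BFGS and
keeps the better likelihood, falling back to Powell when neither converges
— without this, nested fits can come back with a spuriously *lower*
likelihood than their null and produce a point mass of p = 1. A
family-only random-effects structure is available by passing
`groups=["family_id"]`. When energy is itself the outcome it is dropped
from the covariate list. Null-calibration checks use replicates of 40
families (80 observations), large enough for the chi-square reference
distribution of the LRT to apply.

## Numerical and design notes

* All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  takes a single seed and is byte-deterministic given it.
* Simulation sizes in the tests and acceptance script (372 MZ / 246 DZ pairs
  for behaviour heritability, 20 seeds for recovery means, 200×10
  configurations for the permutation floor, cohorts of 50–1000 families
  elsewhere) were chosen as the smallest scales at which the targeted
  quantities are statistically stable.
* Degenerate inputs are first-class: empty records, all-excluded batches,
  participant groups with no skippers, constant nutrient columns and
  single-zygosity pair sets all return flagged results or informative
  errors rather than silently propagating.

## Known limitations

* Observed-scale (not liability-scale) heritability for binary traits.
* No gene–environment interaction, multivariate twin models or extended
  pedigrees.
* The quality scorer's structural completeness rules are a deterministic
  proxy for human judgement and will differ from dietitian consensus on
  edge cases.
* Word-cloud rendering and layout aesthetics are out of scope; frequency
  tables and edge lists are the canonical outputs.
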