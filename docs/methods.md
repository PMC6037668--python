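# Methods

This note records the statistical models, the synthetic-cohort design,
the numerical choices and the known limitations of `microscan`.

## Synthetic cohort model

The generator produces a twin-structured cohort emulating an older,
mostly female population profiled by 16S sequencing: age ~ N(60, 12²)
years, BMI ~ N(26, 5²) kg/m², 89% female (twins share sex), lognormal
sequencing depth (median ≈ 22,000 reads), and categorical technical
factors (3 DNA extractors, 2 collection methods, 8 sequencing runs).

**Binary phenotypes.** Statuses come from a latent Gaussian copula. Each
phenotype has a standard-normal latent Z with a correlation matrix chosen
so that, after thresholding at the quantile matching each target
prevalence, selected pairs realize requested Phi coefficients; the latent
correlation for each (prevalence₁, prevalence₂, φ) triple is solved by
Brent's method on the bivariate normal CDF, and the assembled matrix is
checked for positive definiteness (an infeasible target raises an error
naming the offending pairs). Twin pairs share a family component of each
latent (default family liability correlation 0.2).

**Planted effects with exact logistic truth.** Z is mapped through its
CDF to a uniform U and then through the logistic quantile function, so
logit(U) is a standard-logistic liability. A planted effect adds
β · x to that liability, where x is the clean standardized trait signal
and β is the effect in log-odds per SD; the case threshold c is solved so
that the mean of expit(βx − c) equals the target prevalence. Consequently
P(case | x) = expit(βx − c) holds *exactly*: the true marginal log-odds
per SD of the clean trait is the planted β itself, which is what makes
analytic power and parameter-recovery studies possible. Phenotypes
without planted effects keep exactly the statuses implied by the copula
threshold. Note that when two phenotypes share a planted trait, the
shared effect adds dependence on top of any copula Phi target for that
pair — deliberate, since that is the disease/co-prescription confounding
pattern the overlap stage exists to exhibit.

**Traits.** Traits come in blocks with equicorrelation ρ (default 0.7) at
both the individual and the family level; a family random intercept
(default intraclass correlation 0.3) makes twins more similar than
strangers. Observed traits add technical structure on top of the clean
signal: a per-(factor level, trait) shift drawn from N(0, 0.3²) for each
of the three batch factors, and a per-trait slope on standardized
log-depth drawn from N(0, 0.15²). Because these additions are independent
across traits, the observed within-block correlation is
ρ / (1 + 3·σ²_batch + σ²_depth); configurations that need a particular
*observed* correlation (e.g. above the 0.8 marker-selection threshold)
set ρ and the technical SDs accordingly. A configurable fraction of
phenotype entries (default 5%) is masked to unknown, emulating incomplete
questionnaires.

**What the generator does not emulate.** Traits are Gaussian, not
compositional: real log relative abundances are zero-inflated, heavy
tailed and sum-constrained, and real correlation structure is not block
diagonal. There is no phylogeny, no read-level noise, and questionnaire
error is limited to missingness (no misclassification). Passing tests
therefore demonstrate correctness of the statistical machinery under a
well-specified model, not robustness to the full messiness of 16S data.

## Trait assembly

Counts collapse by summing over taxa sharing the lineage prefix through
the requested rank; taxa lacking a complete assignment at that rank are
excluded, so collapsed totals can fall below the sample depth. Log
relative abundances use a pseudocount ε (default 0.5) applied as
log((c + ε)/(N + εK)) with K taxa — the adjusted proportions still sum to
one per sample. Shannon diversity defaults to base 2 (bits);
phylogenetic diversity is accepted only as a precomputed input column
because it requires a tree. PCoA is classical scaling (scikit-bio);
axes with non-positive eigenvalues — possible for non-Euclidean
distances — are not used, and requesting more axes than exist yields zero
columns.

## Marker selection

Edges use |ρ| > threshold (strict inequality, default 0.8) on pairwise
Spearman correlations: a strongly negatively correlated trait is equally
redundant, so absolute values are the default (`absolute=False` gives
signed edges). Degrees are recomputed on the surviving subgraph at each
iteration, and ties at maximum degree are broken uniformly at random
from the run seed with the tie size logged. The output is checked to be
an independent dominating set; the greedy heuristic is the contract, not
minimum-dominating-set optimality (which is NP-hard).

## Residualization and scan

Scan variants share sequencing depth as a fixed covariate and differ in
age/BMI: `full` (both), `no_bmi`, `no_age`, `neither`. Fixed covariates
are standardized internally (residuals are unchanged by affine rescaling
of regressors).

Two engines produce confounder-adjusted traits:

* `lmm` (default): per trait, a linear mixed model with the batch factors
  (extractor, collection method, run, sex) as fixed dummies and a
  Gaussian random intercept for family — the many-small-groups setting
  MixedLM handles natively. Conditional residuals subtract both the fixed
  fit and the family BLUP. A fully crossed random-effects formulation
  with all five grouping factors as variance components was rejected on
  numerical grounds: with hundreds of family levels expressed as
  variance-component dummies the fit is slow and frequently fails to
  converge, while the few-level technical factors are estimated
  equivalently (for residual purposes) as fixed effects. Traits whose
  mixed fit fails fall back to the OLS projection with a logged
  downgrade.
* `ols`: one projection of all traits onto the span of the fixed design
  (batch factors as dummies, family ignored). It removes the same
  technical structure, runs orders of magnitude faster, and is the
  engine used inside replicate-heavy simulation studies; the family
  intercept it leaves in the residual is part of the biological signal,
  not a batch artifact.

Each (phenotype, trait) pair is fit by maximum-likelihood logistic
regression with a Wald test on the slope. Unknown statuses and missing
traits are excluded pairwise; pairs with no cases or no controls are
reported with status `skipped`; perfect separation and non-convergence
are flagged (`separated`, `unconverged`) rather than silently dropped.
Benjamini–Hochberg runs over converged tests only (m reduced
accordingly), by default jointly across the full phenotype × trait matrix
of a scan variant; per-phenotype scope is available by configuration.
Antibiotic use is treated as a scanned phenotype, never as a covariate,
so its own microbiota associations remain visible alongside the other
medications.

## Association clustering and bootstrap support

Coefficients from tests with p ≥ α (default 0.05, strict) are set to
zero; traits and phenotypes left without any nonzero coefficient are
dropped. Cosine distance d = 1 − u·v/(‖u‖‖v‖) is used because it depends
on profile direction, not magnitude, and degrades gracefully under the
sparsity the zeroing introduces; a zero vector (possible inside bootstrap
resamples) gets similarity 0, hence distance 1, to everything.
Complete-linkage merges are deterministic (scipy's ordering on merge
candidates); the arcsine transform (rescaled by max |β| only when that
exceeds 1) is for heatmap display only and never feeds clustering.

Multiscale bootstrap resamples the profile coordinates — the phenotype
columns when clustering traits — with replacement at 10 ratios r spaced
over [0.5, 1.4], recomputing distances and linkage each time, and records
the recovery frequency BP_r of each original cluster (n_boot per scale,
default 1000 in library use, 10 scales). Per cluster, weighted least
squares fits Φ⁻¹(1 − BP_r) = v√r + c/√r with delta-method weights
n_boot·φ(z)²/(BP(1 − BP)), and AU = 1 − Φ(v − c); clusters with AU > 0.95
(AU-based p < 0.05) are flagged significant. Degenerate cases: a cluster
recovered in every replicate at every scale gets AU = 1 and one never
recovered gets AU = 0 (the regression carries no information there and
the limits are the correct ones); partial saturation is handled by
clamping BP to [1/(B+1), 1 − 1/(B+1)]; a single resampling scale yields
BP only, with AU undefined and flagged.

## Overlap analysis

All disease × medication pairs are scored: Phi on pairwise-complete
samples with a χ² p-value (n·φ² ~ χ²₁, no continuity correction — exact
tests are out of scope), FDR over all pairs in the table, and the Jaccard
index of the two phenotypes' nominal association sets. Eligibility
requires FDR-significant Phi and at least `min_assoc` associations on
both sides (default 10, proportioned to a ~68-marker scan; the reference
synthetic analysis scans ~17 markers and scales this to 2). A Jaccard of
two empty sets is defined as 0 with a warning; it cannot arise for
eligible pairs.

## Pipeline and determinism

One user seed fans out to per-stage seeds through numpy `SeedSequence`
spawn keys, so stages are individually re-runnable and reproducible. No
timestamps are written; two runs with the same config and seed are
byte-identical, and `manifest.json` records the seed, a SHA-256 of the
canonical config and package versions. The reference synthetic analysis
uses n = 1000 individuals (300 twin pairs), 20 phenotypes, 68 traits in
17 blocks and 500 bootstrap replicates per scale; validation studies use
100 replicate cohorts (null calibration, 20 × 68 tests at n = 1000),
200 replicates (planted-effect power at n = 2000), 20 seeds (block
recovery) and 1000 bootstrap replicates (cluster recovery) — sizes chosen
so the full validation suite completes in minutes on one CPU while Monte
Carlo error stays well inside the tested tolerances.

Calibration is judged on the replicate-averaged nominal rejection rate:
with ~1400 correlated tests per replicate the per-replicate rate has a
standard deviation near one percentage point from shared-trait dependence
alone, so the averaged rate (standard error ~0.1 pp) is the quantity that
actually tests calibration. Kolmogorov–Smirnov uniformity of null
p-values is checked on cohorts with independent traits, because the KS
null distribution assumes independent observations; under correlated
blocks the KS statistic inflates without any miscalibration of the
individual tests.

## Known limitations

Raw-read processing (chimera removal, OTU clustering, taxonomy
assignment, UniFrac) is upstream of this package; it starts from count
tables and distance matrices. The scan tests one trait at a time —
no multivariable or longitudinal modelling — and the cross-sectional
design cannot attribute overlapping associations to the disease or its
treatment. Wald p-values are asymptotic and can be optimistic for very
rare phenotypes with few cases; such pairs should be read alongside their
`n_cases`. The OLS residualization engine ignores the family intercept,
which is conservative for batch removal but leaves twin correlation in
the residuals; the mixed-model engine is preferred for final analyses.
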