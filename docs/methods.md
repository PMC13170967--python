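# Methods

`kennelquant` implements the quantitative-genetic analysis pipeline used by
kennel-club health schemes for ordinal clinical grades: pedigree-based
variance-component estimation on a latent liability scale, BLUP breeding
values with accuracies, multivariate genetic correlations, pedigree
principal components and cohort-level epidemiological summaries. This note
documents the models, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Pedigree handling

Registry pedigrees are read as CSV (`id, sire, dam, sex, dob, colour, sbn,
registration`). Parent identifiers that never appear as rows become founder
records with sex inferred from the parental role, since registry exports are
often parent-referencing. Inconsistencies are repaired by *nulling the
offending parent link* — never by deleting records, which would orphan
phenotypes — with machine-readable reason codes: `self-parent`,
`sex-conflict` (an id used both as sire and dam loses all parental links),
`chronology` (offspring born on or before a parent's birth date), and
`cycle` (one cycle-closing link nulled at a time until a topological order
exists). The repaired pedigree is a fixpoint: validating it again yields an
empty log.

Inbreeding coefficients follow the Meuwissen–Luo ancestor-traversal
algorithm: for each animal the additive relationship between its parents is
accumulated with gene-flow coefficients and Mendelian-sampling variances
d_i (1 for unknown-parent founders, 0.75 − 0.25 f_known with one known
parent, 0.5 − 0.25(f_s + f_d) with both). Unknown parents are treated as
unrelated base-population founders; unknown-parent groups and metafounders
are out of scope. The same d_i drive Henderson's rules for the sparse
A⁻¹ and the sparse Cholesky factor L (row i = half the parent rows plus
√d_i on the diagonal), so f, A⁻¹ and L are exactly mutually consistent. A
dense tabular recursion for A (capped at n = 2000) is retained purely as a
brute-force oracle; the test suite checks f against diag(A) − 1 to 1e−12,
A⁻¹·A against I to 1e−8 and L·L′ against A to 1e−10 on random pedigrees.

## Liability transform

An ordinal grade with observed category proportions p₁…p_J is mapped to the
conditional means of a standard-normal liability between thresholds
z_j = Φ⁻¹(p₁+…+p_j):

    y_j = (φ(z_{j−1}) − φ(z_j)) / (Φ(z_j) − Φ(z_{j−1})).

Scores have zero mean under the observed distribution and between-category
variance c = Σ p_j y_j² ≤ 1. Empty categories are dropped before threshold
computation. The scores are used raw — variance *ratios* are scale
invariant — and proportions are computed per trait within the analysis
dataset (all records, not one per dog).

**Attenuation.** Coarsening a Gaussian liability into J categories and
replacing each grade by its conditional mean shrinks covariances between
relatives by c² while the variance shrinks only to c, so the
transform-then-linear-model estimand is approximately

    h²_transformed ≈ c σ²_a / (σ²_tot − c σ²_as),

below the latent-scale ratio (for the default four-category frequencies,
c ≈ 0.80 and h² 0.45 → ≈ 0.34). This is a property of the
transform-then-linear-model design itself, not an estimation error; the
test suite verifies that the fitted ordinal-pipeline h² tracks this
closed-form prediction. Parameter-recovery claims about the REML machinery
are therefore made on continuous (latent-scale) records, which the
generator produces natively; the ordinal path is tested for exactly the
attenuation it should show. Threshold-model (probit) REML, which would
remove the attenuation, is deliberately out of scope.

Binary clinical statuses: respiratory grades 2–3 are affected; nostril
stenosis moderate/severe is affected; body condition score ≥ 7 (9-point
scale) is obese.

## Univariate animal model

For transformed records y:

    y = Xβ + Z₁a + Z₂pe + Z₃as + f(age) + e,
    a ~ N(0, A σ²_a),  pe ~ N(0, I σ²_pe),  as ~ N(0, I σ²_as),
    e ~ N(0, I σ²_e),

with sex (male reference) and scaled linear age always fixed; colour group
(breed-standard reference), show-breeding score, year of birth/test,
ordinal dates, inbreeding, obesity and body condition attachable as
covariates. Records with a missing assessor receive a unique singleton
level each, contributing nothing to the assessor variance. The age smooth
f(age) is a natural cubic spline fitted as a random term: the
truncated-power natural basis on interior knots at distinct-age quantiles
(default min(50, distinct ages − 2)), residualized against {1, age} so the
fixed linear trend is not double counted, columns scaled to mean-square one
so σ²_spline reads as a per-record variance. Degenerate fixed columns
(single-sex data, constant covariates) are dropped to preserve full rank.

### REML

Estimation is average-information REML on the mixed-model equations,
assembled sparse and factorized dense (LAPACK Cholesky). Per iteration: the
AI matrix from working variates (one extra MME solve per parameter), exact
score traces through the inverse coefficient matrix, a Newton step with
step-halving, and an expectation–maximization update as ascent-guaranteed
fallback. Variance parameters sitting at the floor (1e−8 of the phenotypic
variance) with negative score are excluded from the Newton step
(active-set handling); covariance matrices are kept PSD by eigenvalue
bending at the same floor. Convergence: |Δ logL| < 1e−8 and max relative
parameter change < 1e−6; non-convergence is flagged, not raised. Standard
errors come from the inverse AI matrix; fixed-effect Wald tests from the
β-block of the inverse coefficient matrix. The engine's likelihood,
gradient, AI matrix and ML likelihood are unit-tested against explicit
dense V/P-matrix formulas.

Model choice mirrors health-scheme practice: each random term is tested by
a likelihood-ratio test with the boundary mixture ½χ²₀ + ½χ²₁ (statistic
floored at zero; equal likelihoods give p = 0.5); nuisance fixed terms are
pruned by backward elimination when removal improves BIC by ≥ 2, with BIC
computed from *maximum-likelihood* fits (direct numerical optimization of
the exact ML log-likelihood over log-variances) because REML likelihoods
are not comparable across fixed-effect sets. Sex, linear age, the additive
term and the spline are never candidates for removal.

Heritability is σ²_a / (σ²_a + σ²_e [+ σ²_pe]), repeatability
(σ²_a + σ²_pe) over the same denominator and only reported when the
permanent-environment term is fitted; assessor and spline variances are
nuisance components excluded from the phenotypic variance. SEs by the delta
method from the AI covariance of the components.

## Breeding values and accuracy

The final model is re-solved at the converged components over the entire
pedigree, so unphenotyped animals obtain EBVs via relatives (an animal with
no information gets exactly 0; an unphenotyped offspring without
descendants gets the parental average). PEV is the additive diagonal of the
inverse coefficient matrix — dense inversion below 2000 equations, batched
sparse solves above — and

    accuracy = √(1 − PEV / ((1 + f) σ²_a)),

clamped to [0,1]; PEV exceeding (1+f)σ²_a beyond rounding is an error. The
printed source for this formula is typographically garbled, so the standard
PEV-based form consistent with "PEV = squared SE of the EBV" is
implemented; reliability (no square root) is available by flag, and cohort
summaries emit both √h² (selection on own phenotype) and √(h²/2) (parental
average) reference thresholds because the reference lines can be read on
either scale.

## Multivariate model

Traits are stacked with u ~ N(0, G⊗A) additive, C⊗I assessor, trait-wise
permanent environment (no pe covariances, and pe only for traits where it
was univariately retained), and residual blocks per *test event* (one dog
on one date): events missing a trait simply contribute a smaller residual
block, which handles trait-wise missingness exactly. Residual covariances
between never-co-observed trait pairs are structurally unidentified and
fixed at zero. The same AI-REML engine estimates all (co)variances; a
one-trait "multivariate" fit reproduces the univariate fit to 1e−5
(regression-tested).

Genetic (and residual, assessor) correlations are covariance over the
geometric mean of variances, SEs by the delta method, significance by a
likelihood-ratio test with the covariance pinned at zero. Phenotypic
correlations are

    r_P = (σ_a,ij + σ_e,ij) / √((σ²_a,i + σ²_pe,i + σ²_e,i)(σ²_a,j + σ²_pe,j + σ²_e,j)),

tested with the exact-t Fisher statistic t = r√(n−2)/√(1−r²), where n is
the number of events with both traits recorded. A fit is flagged unstable
when it fails to converge or a genetic covariance has degenerate (zero) or
overwhelming (> 0.75 of the variance product) information.

## Pedigree PCA

Principal components of the column-centred Cholesky factor L (equivalent to
double-centring A up to rank-one terms; centring is a flag). A seeded
Gaussian sketch with oversampling 10 and two base power iterations is
refined with further power iterations until the top-k subspace moves by
less than `tol` (default 1e−8 radians): relationship-matrix spectra decay
slowly (adjacent singular-value ratios ≈ 0.95 on simulated pedigrees), so a
fixed two-iteration sketch is reproducible but only ~0.1-radian accurate,
while the refined sketch matches the dense SVD to < 1e−6 at n ≈ 300.
`tol=None` restores the fixed-iteration sketch. Scores are deterministic
for a fixed seed, with sign fixed by the largest-magnitude loading.

## Cohort statistics

Prevalence uses one status per dog from the first available grade
(records-based available by flag). Odds ratios come from logistic
regression (statsmodels GLM, binomial/logit), categorical predictors
dummy-coded against a caller-chosen reference, Wald 95% CIs by
exponentiating β ± 1.96 SE; pooling across breeds adds breed as a fixed
covariate. Complete separation is detected and flagged (infinite OR), not
raised. Parent–offspring regression reports h² = slope (midparent) or
2·slope (single parent) with OLS SEs, requiring ≥ 10 complete pairs.
Litter summaries define a litter as a unique (sire, dam, date-of-birth)
triple and compare litters per tested versus untested sire with a Welch
two-sample t-test; grade progression compares first and last grade per
repeatedly tested dog. Rank-based between-breed tests are ordinary
`scipy.stats` calls and not part of this package's surface.

## Synthetic data

The generator mirrors the generative model exactly: non-overlapping
generations (a simplification — real registries overlap; the estimation
code never assumes otherwise), random or EBV-assortative mating, additive
values u = L z σ_a (so cov(u) = A σ²_a, with cross-trait covariances via a
genetic correlation matrix), per-dog permanent-environment effects,
shared assessor effects, fixed sex and linear-age effects, Gaussian
residuals, and thresholds cutting the latent liability into four grades.
Default conditions: σ²_a = 0.45, σ²_pe = 0.16, σ²_as = 0.30, σ²_e = 0.39
(h² 0.45, repeatability 0.61), category probabilities
(0.454, 0.390, 0.126, 0.030) giving 15.6% clinical prevalence; a second
trait with h² 0.39, categories (0.062, 0.426, 0.452, 0.060) and genetic
correlation 0.6; sex effect −0.33 (females lower), age slope 0.05 per SD;
records per dog averaging 1.25 (80/15/5% for 1/2/3 records); 30 assessors
with 10% of records missing the assessor identity. One master seed streams
every draw; outputs are bit-reproducible and fixture bundles round-trip
through the parsers losslessly.

What the synthetic tests show: the estimation machinery recovers known
variance components, correlations and accuracies under the model's own
assumptions, at realistic sizes. What they do not show: robustness to
pedigree errors, assortative participation (health-scheme testing is
voluntary and correlated with show breeding), overlapping generations,
selection over time, or non-Gaussian liabilities — all properties of real
registry data that no simulation from the fitted model can certify.

## Problem sizes and runtime

Validation replicates use ~500 tested dogs (≈ 630 records) per univariate
replicate and ~420 dogs per trait (≈ 800 records) per bivariate replicate,
with 20 replicates for recovery claims and 500 for null calibration; these
sizes keep a full validation run in minutes on one CPU while leaving
informative standard errors (h² SE ≈ 0.09). The mixed-model equations at
these sizes are a few thousand equations, well inside the dense-factorization
regime; the engine's only scale-sensitive step is the dense inverse used
for score traces, O(m³) in the number of equations.

## Known limitations

- Transform-then-linear-model, not a probit threshold model: transformed-
  scale heritabilities are attenuated as described above.
- No genomic relationships, unknown-parent groups or metafounders.
- The multivariate EM fallback uses complete-data-style residual updates
  under missingness; it is only a fallback and every accepted step is
  ascent-checked against the exact likelihood.
- The boundary-mixture LRT is asymptotic; at modest family counts the
  empirical size of a 5% test runs slightly conservative (≈ 4% in the
  package's own null calibration), consistent with the known finite-sample
  behaviour of variance-component LRTs.
- Accuracy summaries assume the variance components are known; uncertainty
  in σ²_a is not propagated into accuracies.

At the validation sizes the REML point estimate of h² runs slightly low
(replicate means ≈ 0.40–0.41 against a latent 0.45), a small-sample
tendency of variance-ratio estimates with several nuisance components;
the 2-SE recovery criteria account for it and the bias shrinks with data
size.
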