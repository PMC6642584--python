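# Methods

## Working model and statistics

The selector operates in a linear quasi-likelihood working model
E(Y | X = x) = x'β with the binary outcome coded +1 (case) / −1 (control)
and centered per study. A linear rather than logistic model is used
deliberately: it makes every quantity the algorithm needs expressible in
sufficient statistics (scores and pairwise covariances) that can be pooled
across studies, and for *marker selection* it ranks SNPs essentially as a
logistic model would. Coefficients are therefore on the standardized-
genotype, linear-score scale and are not interpretable as log odds ratios;
the package treats them as a selection device and a risk-score direction,
not as effect estimates.

Genotypes are standardized per study and per column over the **observed
entries**: subtract the observed-entry mean and scale so the observed-entry
sum of squares equals the observed-entry count. Columns that are constant
within a study (or have fewer than two observations there) have no defined
scale; they are flagged degenerate and treated as unavailable in that
study, i.e. dropped from that study's availability set.

All counts are observed-entry counts: n_lj is the number of individuals in
study l with SNP j observed, n_j = Σ_{l∈K_j} n_lj, and n_jk counts
individuals with both members of a pair observed. When no entries are
missing these reduce to the whole-study counts, and per-SNP availability
reduces to platform membership. This single convention covers both sources
of missingness (platform non-overlap deletes whole column blocks;
post-imputation QC deletes single entries) with one code path.

## The pairwise-covariance update

The boosting candidate score is

    γ_j = Δ_j − (1/n_j) Σ_{k: β_k≠0} β_k · C_jk .

C_jk must estimate the cross-product sum Σ_{l∈K_j} Σ_i x_lij·x_lik, which
is not computable verbatim when SNP k is missing for some of those
individuals. The package uses the pairwise-complete plug-in

    C_jk = (n_j / n_jk) · Σ_{pairwise-observed i} x_ij·x_ik ,  C_jk = 0 if n_jk = 0,

i.e. the mean cross-product over individuals observing both SNPs, scaled
back up to n_j. This uses every observed pair, is exactly the literal
double sum when data are complete, and gives C_jj = n_j identically by
standardization. Equivalently, the correction term in γ_j is
Σ_k β_k · (pairwise mean of x_j x_k). Note C is not symmetric — the j-side
scale n_j/n_jk differs from the k-side n_k/n_jk — only the underlying raw
sum is. Information on SNP k from individuals where j is unobserved is
never used for updating j, matching the pooled-score restriction to K_j.

A caveat of pairwise-complete estimation: the implied "covariance matrix"
need not be positive semi-definite under adversarial missingness patterns.
The boosting path only evaluates bilinear forms against small active sets
and applies shrinkage, which in practice keeps the path stable; the
complete-data limit is exact.

## The boosting loop

Start at β = 0. Each of M steps selects j* = argmax γ_j² (the score
statistic), breaking exact ties by lowest superset index — the superset is
ordered by first appearance across studies in input order, so results are
reproducible — and updates β_{j*} += ν·γ_{j*}. If every γ_j is exactly
zero the loop stops early (converged sentinel); an optional cap on the
number of distinct selected SNPs is available as an alternative stop.

Implementation: Δ is computed once per dataset; γ is maintained
incrementally (γ ← γ − update · pairwise-mean-column of j*), and the
pairwise column of a SNP is computed on first activation and cached. Cost
is O(M·p + n·p·|active|) per fit instead of O(M·n·p²).

Defaults M = 200, ν = 0.05 (ν = 0.1 is the other setting used in the
reference analyses). On complete data the path equals classical
residual-refitting componentwise boosting coordinate-for-coordinate; the
test suite asserts this to 1e-10 per coordinate over 100 random shapes,
and `baselines.residual_boost_oracle` keeps the literal residual
implementation as an independent oracle (it refuses incomplete data).

## Stability selection

B subsamples (default 100) of fraction 1/2 are drawn without replacement,
**stratified per study**: floor(n_l/2) individuals per study. The
stratified choice keeps small studies represented in every subsample; a
non-stratified pooled-roster mode is available behind a flag for
sensitivity checks. Each subsample is treated as a dataset in its own
right: availability, counts and standardization are all recomputed inside
it. A study subsample containing a single outcome class is redrawn (up to
5 retries) and then raises.

"Selected" means a nonzero coefficient after the final step M, consistent
with the definition of q as the average number of selected covariates at
step M over the B subsamples. IF_j is the fraction of subsamples selecting
j, always a multiple of 1/B. The per-family error bound
E(V) ≤ q²/(p·(2π_thr−1)) is reported on a grid of thresholds
π_thr ∈ (0.5, 1) (default 0.6–0.9) rather than a single value, since each
threshold corresponds to a different type-1 error level; a selection is
flagged FWER-controlled at α only when the bound is ≤ α.

Seeding: one master seed; per-subsample generators are spawned via
`numpy.random.SeedSequence`, so results are bitwise reproducible and the B
fits could be parallelized without changing results.

## Univariate baseline

The univariate reference is a score test in the same linear working model:
z_j = √n_j · Δ_j / s_y with s_y the RMS of the centered outcome over the
rows observing j, two-sided normal p-value. This keeps the baseline
self-consistent with the selector's working model and avoids hidden
covariate-adjustment assumptions; a per-SNP pooled logistic Wald test
(statsmodels) is available as an option. Bonferroni correction uses
α / (number of tests).

## Synthetic panels

The generator emulates the structure of pooled consortium data, not its
biology:

- **Genotypes**: two independent "haplotype" draws from a latent Gaussian
  with block-equicorrelation ρ, thresholded at the (1−MAF) quantile, summed.
  Margins are approximately Binomial(2, MAF) (Hardy-Weinberg); LD is
  positive within blocks, zero across. Defaults: MAF ~ U(0.1, 0.4), blocks
  of 10 SNPs at ρ = 0.3 — common-variant panels with moderate local LD.
- **Outcome**: additive log-odds model P(case) = expit(intercept + Σ β_j g_j);
  the intercept defaults to centering the linear predictor so the case
  share is near 1/2 (case-control-like balance). A target case fraction
  can instead be hit exactly by oversampling and subsampling.
- **Partial overlap**: per-study platform masks delete whole columns; the
  canonical mask keeps 83.64% of the superset (13,349/15,961 — the
  coverage ratio of the smaller genotyping platform in the motivating
  data). Entry-level missingness is MCAR uniform (default 2% in the
  two-study scenario); the method claims nothing about informative
  missingness, and MCAR suffices to exercise the pairwise-complete path.

What the generator does **not** emulate: realistic recombination/LD decay,
population stratification, relatedness, genotyping batch effects, or
informative (MAR/MNAR) missingness. Passing tests on these panels show the
estimator's algebra and its pooling behaviour are right, not that the
method is robust to confounding in real consortium data.

## Study designs used in the end-to-end checks

Problem sizes are desk-scale replicas of the motivating designs, chosen
once as the package's standard experiment sizes:

- **Recovery**: studies of 1600 + 400 individuals, p = 500, five causal
  SNPs at OR 1.6 per allele spread across distinct LD blocks, small study
  masked at 83.64%, 2% entry missingness; B = 50, M = 100, ν = 0.1.
- **Pooling vs complete case**: one complete cohort of 1800, split 8:1,
  small part masked at 83.64%; same boosting/stability settings; causal
  inclusion frequencies compared between the reduced (both studies) and
  partial (large study only) analyses over 20 replicates.
- **Null calibration**: single-study no-signal panels, n = 400, p = 200,
  B = 50, 50 replicates; realized counts above each IF threshold compared
  with the E(V) bound at the observed q.

## Numerical choices and edge cases

- Ties at argmax γ²: lowest superset index (measure-zero on continuous
  data; makes duplicated-column fixtures deterministic).
- SNPs with no observed entries anywhere get Δ = 0 and can never be
  selected.
- γ is maintained incrementally; the complete-data equivalence tolerance
  of 1e-10 absorbs the (≈1e-15-level) floating-point difference against
  the recompute-residuals oracle.
- Genotype validation is strict ({0, 1, 2, missing}); parse errors name
  the offending row and column.
- The CSV dialect stores missing entries as empty fields; PLINK `.raw`
  input maps phenotype 1/2 to control/case and strips trailing
  counting-allele suffixes from SNP names.

## Limitations

- Selection only: coefficients are not calibrated effect sizes, and no
  confidence intervals are provided beyond the E(V)/FWER statement.
- The E(V) bound inherits the exchangeability assumption of stability
  selection; with q close to p (tiny panels, generous M) it is vacuous.
- M and ν are fixed in advance, not cross-validated, matching the
  reference analyses.
- Pairwise-complete covariance estimation assumes missingness carries no
  outcome information (MCAR-like); nothing in the algebra corrects for
  informative missingness.
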