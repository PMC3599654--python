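# Methods

This note records the statistical model behind `mwaspca`, the defaults and
why they were chosen, the numerical conventions, and what the simulator does
and does not emulate.

## Block creation

Correlation between neighboring CpG sites has two distinct scales: in
enrichment sequencing (MBD-seq/MeDIP), sites within one fragment length
(~100–200 bp) are measured from largely the same reads and correlate near 1;
beyond that, regional co-methylation produces weaker biological correlation.
Blocks are therefore built in two cascaded stages with different thresholds,
but the algorithm is identical in both stages and purely empirical — no
fragment-length model is used, only the observed correlations.

The merge is a greedy left-to-right scan within each chromosome (blocks
never span chromosomes). A block opens at the leftmost unassigned site.
For each next site in coordinate order, its mean Pearson correlation *c*
with the current members is computed; the site is tentatively added, and the
block closes when either

* the mean correlation over all unordered member pairs falls below *t₁*, or
* *n_t* consecutive sites have been added with *c* < *t₂*.

On closing, the trailing run of below-*t₂* sites (and the site that broke
*t₁*, if any) is removed, and the scan restarts at the first removed site.
The stop rules admit more than one growth procedure; this trimming variant
was chosen because it keeps the closed block internally coherent (sites that
triggered the stop are not kept inside it) and makes the *n_t* counter well
defined as "consecutive trailing additions". "Average correlation in the
block" is taken literally as the mean over all member pairs, not the mean of
candidate-to-block correlations.

Defaults: stage 1 *t₁* = *t₂* = 0.9, stage 2 *t₁* = *t₂* = 0.6 (the
fragment-scale and biological-scale thresholds used in production MWAS
runs), *n_t* = 2 (a repository choice: tolerating one stray low-correlation
site but not two avoids chaining unrelated regions through a single noisy
site). Zero-variance sites have no defined correlation; they are treated as
correlation 0, so they always end up as singleton blocks rather than
propagating NaN. The block value is the arithmetic mean of member sites per
subject, so per-subject totals are preserved (Σ blocks mean × size = row
sum). Block-map files are BED-like (0-based half-open spans; the in-memory
representation is 1-based inclusive and the writer converts); a singleton
block's undefined mean correlation is serialized as `.`.

## PCA via the similarity matrix

With X the column-centered n × p matrix, the PCA of C = XᵀX/(n−1) is
obtained from M = XXᵀ/(n−1): eigenvalues agree (λᵢ = αᵢ), scores are
PCᵢ = uᵢ√((n−1)αᵢ) and loadings vᵢ = Xᵀuᵢ/√((n−1)αᵢ). The test suite
verifies this equivalence against a direct eigendecomposition of C on
hundreds of random matrices, as well as the self-consistency X vᵢ = PCᵢ and
Σαᵢ = trace(C).

Numerical conventions:

* **Rank cutoff** — components with αᵢ ≤ 1e−9 · α₁ are discarded as
  numerically null (appropriate for double-precision symmetric
  eigensolvers); requesting more components than the rank truncates with a
  warning.
* **Sign convention** — eigenvectors are only defined up to sign; the entry
  of largest magnitude in each uᵢ is forced positive, making output
  deterministic across BLAS backends.
* **Chunking** — XXᵀ is assembled from (row-chunk, col-chunk) subject-pair
  products. Column means (and SDs in correlation mode) are computed once
  over the full sample before any chunking, so the result is exactly
  independent of chunk size and of job order; each product can be persisted
  to a scratch file keyed by its chunk pair, which is the contract used for
  running chunk jobs as separate cluster processes. Default chunk size 350
  subjects balances memory against job count at typical MWAS sample sizes.
* **Correlation mode** — columns are additionally scaled to unit sample SD
  (ddof = 1); zero-variance columns are dropped with a warning (in
  covariance mode they are retained as zero columns). When measured
  covariates are regressed out, residualization happens first and
  standardization second, so "correlation mode" means correlations of the
  adjusted data.
* **Residualization** — ordinary least squares of every site on intercept +
  selected covariates; the design must be full rank; residuals are exactly
  orthogonal to the covariates and the operation is idempotent.

The scree (eigenvalue-gap) criterion counts the components before the
largest consecutive ratio αᵢ/αᵢ₊₁ among the top 10. This is deliberately
simple; it recovers planted factor counts reliably when signal eigenvalues
stand clear of the Marchenko–Pastur bulk, and it is what the automated
factor-count checks use.

## Association testing and genomic control

Each site (or block) is tested by multiple linear regression of the
phenotype on [intercept, site, covariates, selected PC scores]; the reported
statistic is the t statistic of the site coefficient with a two-sided
p-value on n − q − 2 degrees of freedom (q = number of covariates). Linear
regression is used even for 0/1 case status — at MWAS sample sizes the
linear-model test of a binary outcome is essentially equivalent to the
score test and keeps the whole sweep closed-form.

The genome-wide sweep is vectorized through the Frisch–Waugh–Lovell
identity: phenotype and all sites are residualized on the shared covariate
design once, and each site's coefficient, standard error and t statistic
follow from scalar products of residual vectors. This is algebraically
identical to per-site OLS (the test suite checks agreement with statsmodels
to 1e−8) and processes chromosomes independently, so execution order cannot
change the table. Rank-deficient sites (constant after adjustment) are
flagged with missing statistics rather than dropped silently.

Genomic control: each two-sided p is mapped to the χ²₁ upper quantile it
corresponds to, and λ is the median of those values divided by the χ²₁
median (0.45494). The transform — rather than squaring the raw t — makes λ
invariant to degrees-of-freedom differences between models and is standard
genomic-control practice; for n in the hundreds the two agree to well below
the reported precision. QQ plots use i/(m+1) uniform order-statistic
expectations. Multiple-testing flags: Bonferroni (level/m) and
Benjamini–Hochberg step-up q-values.

## The confounder simulator

The generator emulates the confounding structure that PC adjustment is
meant to remove, and nothing else. For subject i with case status yᵢ
(fixed counts: 500 cases, 500 controls by default) and K = 5 factors:

* continuous factor: F = b·y + m, m ~ N(0, σ²), defaults b = 4, σ = 10,
  giving corr(F, y) = ½b/√(¼b² + σ²) = 2/√104 ≈ 0.196;
* dichotomous factor: F ~ Bernoulli(p₁ = 0.6) for cases, Bernoulli(p₂ = 0.4)
  for controls, giving corr(F, y) = ½(p₁−p₂)/√(p̄(1−p̄)) = 0.2;
* methylation: x = a + Σₖ wₖ F l + e with base level a ~ U(0, 100), noise
  e ~ N(0, δ²), δ = 40, and l ∈ {0,1} the influence indicator — factor k
  covers every site of chromosomes 2k−1 … 2k+1, so each factor spans three
  chromosomes and adjacent factors share exactly one. Site counts per
  chromosome are Poisson(4,000) over 22 chromosomes; the whole matrix is
  shifted by its global minimum so values are non-negative like
  coverage-derived scores.

The per-site weight wₖ is 1 for continuous factors and
`dichotomous_effect` = 20 for dichotomous ones. This calibration makes a
dichotomous confounder carry the same covariance with case status through
the sites as a continuous one (20 × ¼(p₁−p₂) = b × ¼ = 1), so the six
continuous/dichotomous mixes produce comparable inflation (λ ≈ 3 without
adjustment); a raw 0/1 factor against noise of SD 40 would be statistically
invisible and could not confound anything.

What the simulator does **not** emulate: read-level sequencing (fragments,
enrichment efficiency, mapping), spatial correlation between neighboring
sites beyond the shared factors (so block creation on simulated data yields
almost all singletons), site-specific variance heterogeneity, and any true
phenotype effect (every simulated association is spurious by construction).
Passing the calibration checks therefore demonstrates correct confounder
capture and test calibration under an idealized factor model — not
robustness to the full noise structure of real enrichment data.

Determinism: one integer seed drives a single PCG64 generator; the same
config is bit-reproducible. Named presets `0c5d` … `5c0d` cover the six
factor mixes, `null` has K = 0.

## Pipeline and problem sizes

The pipeline planner turns a parameter file into ordered stages whose jobs
are independent within a stage (per chromosome for blocks and association,
per subject-chunk pair for XXᵀ). Sequential execution runs the identical
command lines in-process; batch mode writes them to one file per stage and
performs no computation (scheduler submission is deliberately out of scope),
and the two modes produce byte-identical tables.

The validation suite runs the calibration checks at the standard study
scale (1,000 subjects × ~88,000 sites; one simulate→PCA→association
replicate takes ~45 s on one CPU). This scale is needed because the
genomic-control factor is a median over tests sharing one realized
phenotype: its replicate-to-replicate SD is ≈ 0.025 at ~9,000 sites but
≈ 0.01 at the full scale, and only the latter supports a ±0.05 calibration
band on a single replicate. Conversely the raw (unadjusted) λ varies ≈ ±0.25
between replicates at any genome size, because the realized factor–phenotype
correlations fluctuate at n = 1,000; headline numbers for the unadjusted λ
are therefore reported as means over a handful of independent replicates.
Supporting checks that do not involve a median (scree factor counts,
factor–phenotype correlations) use reduced genomes or factor-only draws.

## Known limitations

* The block-growth procedure is one consistent realization of the stop
  rules; other trimming conventions (e.g. keeping the t₁-breaking site)
  would produce slightly different partitions.
* λ inherits the discreteness of strongly categorical designs: with five
  dichotomous covariates and a binary phenotype, adjusted λ sits ~0.98
  rather than exactly 1.
* No mixed models, logistic regression, or region-level tests beyond block
  means; no missing-data handling (`NA` cells are rejected at load).
* The eigensolver is exact and O(n³) in subjects; it assumes n in the
  thousands, not the millions.
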