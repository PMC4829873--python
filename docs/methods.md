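# Methods

## The association model

For each gene *g* the package fits a linear model with the continuous
phenotype as response and that gene's normalized expression as predictor:

    trait_i = β₀ + β₁ x_gi + Σ_p γ_p covariate_pi + ε_i ,   ε_i ~ N(0, σ²)

and tests H₀: β₁ = 0. Orienting the model this way — rather than the
count-model convention of treating expression as the response — is
deliberate: phenotypes like body-mass index or milk yield are outcomes of
gene activity, they are measured on a continuous scale where a Gaussian
error model is defensible once replicate numbers are moderate, and the
orientation admits covariate adjustment with ordinary regression
machinery. The scan API does not offer the reversed orientation.

The predictor is log2 TMM counts-per-million (below), which is
approximately Gaussian per gene; the Gaussian assumption that actually
matters, though, is on the *residuals* of the trait, and the package
ships a genome-wide Shapiro–Wilk screen of per-gene OLS residuals
(`TagAssociation.check_normality`) so the assumption is checked rather
than presumed. Flagged genes (constant residuals) are excluded from the
screen's FDR adjustment.

### Ordinary least squares

Standard OLS per gene; the slope's standard error uses the unbiased
residual variance and the inverse Gram matrix; p-values come from the
central t distribution with n − p degrees of freedom. A numerically zero
residual sum of squares (interpolating fits, constant response) makes the
test degenerate: the statistic and p-value are reported as NaN when the
slope is also (numerically) zero, and as ±∞ / 0 otherwise.

### Huber-robust regression

The M-estimator minimizes Σ ρ(r_i) with the Huber loss — quadratic
within k·σ, linear beyond — fitted by iteratively reweighted least
squares:

1. initialize at the OLS fit;
2. σ̂ = median(|r − median r|) / 0.6745 (MAD, consistent for the
   Gaussian σ);
3. w_i = 1 if |r_i| ≤ k·σ̂ else k·σ̂/|r_i|;
4. weighted least-squares refit; repeat from 2 until every coefficient
   changes by less than tol·max(1, |coefficient|), tol = 1e-8, or 100
   iterations (non-convergence is recorded on the fit, not raised).

The tuning constant defaults to k = 1.345, the classical value giving
95% efficiency under Gaussian errors; smaller k is more robust but
treats mild points as outliers. The scale is re-estimated *every*
iteration, matching the behaviour of the standard robust-regression
implementations this estimator follows. A zero MAD at any iteration marks
the gene degenerate; in a scan such genes become flagged rows rather than
aborting the run.

Inference is a Wald-type t test: with ψ(u) = clip(u, −k, k),

    Var(β̂₁) = σ̂² · [Σ ψ(r_i/σ̂)² / (n−p)] / [mean ψ′(r_i/σ̂)]² · (XᵀX)⁻¹₁₁

referred to t with n − p degrees of freedom. The exact reference
distribution for robust tests in small samples is genuinely debatable;
n − p is the conservative conventional choice, and when no residual
exceeds the threshold the whole procedure collapses exactly onto the OLS
t test (this is asserted in the suite, as is the k → ∞ limit at the
whole-scan level). The test is a t-form single-coefficient Wald test;
numerical parity with F-type robust-test implementations elsewhere is
not claimed.

### Batched evaluation

Genome-wide scans evaluate the per-gene models in lockstep across genes
(stacked designs, batched normal equations, per-gene IRWLS with
convergence masking) so that permutation sweeps are feasible; the
single-gene functions `fit_ols` / `fit_huber_irwls` are the reference
implementation and the suite asserts the two paths agree to ~1e-8 on
every reported quantity, with and without covariates.

## Normalization

TMM scaling factors against a reference sample: the reference is the
sample whose 75th-percentile CPM is closest to the cross-sample mean of
that quantity (ties broken by sample order, for determinism). For sample
k vs reference r, over genes positive in both, M = log2 ratio of library-
scaled counts and A = mean log2 abundance; the top/bottom 30% by M and
5% by A are discarded (rank rule `floor(n·trim)+1 … n−floor(n·trim)`,
average ranks on ties) and the factor is the inverse-asymptotic-variance
weighted mean of surviving M values, `2^(Σ M/v / Σ 1/v)` with
`v = (N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r)`; factors are rescaled to
geometric mean 1. Proportional columns short-circuit to factor 1 (this
also guards the degenerate case of a single gene carrying a whole
library, where the precision weight is infinite). The implementation was
cross-checked against the canonical R implementation once during
development (agreement to 7 digits); the shipped tests use an
independently coded step-by-step oracle instead so the suite is
self-contained.

Expression values are `log2((y + 0.5) / (N·f + 1) · 1e6)` — CPM on
TMM-effective library sizes with a prior count of 0.5 so zeros stay
finite. No low-expression filter is applied by default (scans run on all
genes); `filter_by_cpm` exists for callers who want one. Both the prior
count and the unfiltered default are package decisions: the expression
transform feeding the regressions is standard practice rather than a
uniquely determined choice.

## Multiple testing and significance rules

Benjamini–Hochberg step-up adjustment, implemented directly (NaN entries
pass through and are excluded from m). Two calling conventions are
supported because both are in real use: adjusted `fdr < α` (default,
α = 0.1 is common for modest cohorts) and raw `p < α` for small studies
where FDR control leaves nothing (`adjust="none"`). Note that step-up
adjustment is *not* idempotent — re-adjusting an adjusted vector can only
raise values; the suite asserts the correct monotonicity property and
equality with a quadratic-time oracle.

## The mock comparison

To estimate how many of a method's discoveries are false without knowing
the truth, the trait (and its derived group label, jointly) is permuted
across samples: every test statistic on the permuted data is null, so
genes significant in *both* the real and the mock scan are overlap one
would also expect from chance. The proportion of false discoveries is

    PFD = |sig(real) ∩ sig(mock)| / |sig(real)|

undefined (and excluded from averages, with a warning) when the real set
is empty. The sweep subsamples n per group (stratified on the binary
group when present; 2n uniform draws for a purely continuous trait),
permutes *within* the subsample — the subsample defines the experiment —
scans real and mock, calls significance at raw p < α (FDR-based calling
available behind a flag), and repeats; per-repeat seeds are spawned
deterministically from the base seed and the grid index, so every grid
point is an independent, bit-reproducible experiment. Summaries are the
mean PFD, its standard error (sample SD / √#valid repeats) and the mean
real significant-set size. Methods enter as plug-ins — any callable
mapping (counts, phenotype) to per-gene p-values — so external
differential-expression tools can be swept through the same harness; the
built-in plug-ins recompute TMM normalization inside every subsample.
Per-repeat plug-in failures are logged and skipped; a failure rate above
10% aborts the sweep.

## The synthetic-data generator

The generator emulates a bulk RNA-seq cohort with a continuous
phenotype, at the scale of a large human study by default: 2,000 genes ×
89 samples. Per-gene base means (CPM scale) are log-normal(μ=3.5,
σ=1.5) (median ≈ 33 CPM with a realistic dynamic range); library sizes
are uniform on 0.5–2 million; counts are negative-binomial with mean
μ_g·N_k/1e6 and variance μ + φμ² — φ is the *dispersion* in the
mean-quadratic convention, default 0.1, i.e. a biological coefficient of
variation ≈ 0.32, typical of bulk tissue cohorts. The trait is assembled
from `n_tags` uniformly chosen driver genes (default 50) as

    trait = β₀ + Σ_drivers effect · (x_g − mean x_g) + covariates + N(0, sd²)

using the *same* log2 TMM CPM transform the scans use, so the configured
effect (default 1.0 trait unit per log2 unit, noise sd 1.0) is exactly
the slope a regression estimates — ground truth is exact, not
approximate, and driver centering only keeps the intercept (default 25,
BMI-like) interpretable. Optional pieces: a binary and/or continuous
covariate with stated coefficients, gross trait outliers (a chosen
fraction of samples displaced by a chosen multiple of the trait SD, sign
random), and dichotomization of the trait at a cutoff into the two-group
design the association approach is meant to replace. Counts, trait,
covariates and outliers all derive from one seed through separate
spawned streams.

What the generator does *not* emulate — and hence what green tests do
not certify about real data: gene–gene expression correlation (counts
are independent across genes given library size), batch effects beyond a
single covariate, gene-length effects, outliers in the *counts* (only
trait outliers are injected), and library-composition artefacts. The
calibration results below are therefore statements about the method's
behaviour under its own assumptions, not about any particular tissue.

## Calibration experiments and problem sizes

The acceptance script and the heavier tests use sizes chosen to keep a
full run in minutes on one CPU while leaving the statistical margins
computable in advance:

- *Null calibration*: one null study (2,000 × 89, no drivers), trait
  dichotomized at the median, mock comparison over {10, 20, 37}
  replicates per group, 200 repeats. The mean PFD at 37 per group is the
  headline number and sits at the nominal 0.05 (tolerance ±0.015; the
  Monte-Carlo standard error at 200 repeats is ≈ 0.002). The robust scan
  satisfies the same bound.
- *Slope recovery*: 40 datasets × 5 drivers (effect 1, noise 1, n=89);
  the mean of the 200 driver-slope estimates is within 0.05 of truth.
- *Outlier advantage*: 10% of samples displaced by 10 trait SDs; over
  50 datasets the robust scan's median absolute slope error is less than
  half the OLS scan's (observed ratio ≈ 0.36).
- *Recall/FDR*: 40 datasets of 500 genes with a single strong driver
  (effect 3); pooled recall > 0.8 at FDR < 0.1 with pooled empirical
  false-discovery proportion < 0.2. A design note: with m equally
  weighted independent drivers the marginal trait–driver correlation is
  bounded by 1/√m, so configurations with many equal drivers cap each
  driver's t statistic near √(n/(m−1)) no matter how large the effect —
  recall experiments need few drivers per dataset to be informative.

## Numerical and design choices

- Convergence of IRWLS is judged on coefficients (relative, 1e-8), not
  on weights; fitting is fully deterministic.
- Missing phenotype values: listwise deletion once per scan (expression
  is complete by construction once counts exist); dropped samples are
  recorded on the model and fits.
- Categorical covariates are dummy coded with the first level as
  reference; rank-deficient designs raise with the collinear columns
  named.
- Per-gene scan failures (constant expression, zero MAD) become flagged
  NaN rows, never scan aborts.
- Result tables are sorted by ascending p-value with the input order
  recoverable from a column; all writers are deterministic and derived
  outputs carry a `#` header with the tool version and parameters.
  Counts and phenotype data files are written plain so read/write
  round-trips are byte-identical.
- The prior count makes log2 CPM scale-stable only up to
  ~1/((4y+2)·ln 2) per cell when everything doubles; invariance checks
  should use counts ≳ 40 for a 0.01 tolerance.

## Known limitations

- The robust Wald test's n − p reference distribution is approximate in
  small samples; its observed null rejection rate at n = 30 is within
  0.02 of nominal in the suite, but very small n (< ~15) is untested
  territory.
- The mock comparison measures *overlap-based* false-discovery
  proportion, which assumes the sampled cohort represents the
  population; it is not an FDR estimate in the formal sense.
- External two-group methods are compared only through supplied per-gene
  p-values (file-based for overlap tables, callable plug-ins for
  sweeps); no count-model DE method is bundled or reimplemented.
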