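# Methods

## Model

For gene `g` with maternal allelic count `M_g` and total allelic
coverage `C_g`, the allelic imbalance point estimate is
`AI_g = M_g / C_g`.  The idealized measurement model is
`M_g ~ Binomial(C_g, AI_g)`.  Technical replicate libraries prepared
from the same RNA reveal that the realized noise exceeds this model:
the per-gene difference of AI estimates between two depth-matched
replicates (ΔAI) is wider than the binomial prediction by an
experiment-specific factor.  That factor — the Quality Correction
Coefficient (QCC) — is modeled as constant across coverage levels, a
choice supported by the near-constant observed/expected quantile
ratios across coverage bins (and deliberately different from fitting a
single beta-binomial overdispersion ρ, which would force overdispersion
to grow with coverage).

### Estimation pipeline (two replicates)

1. *Depth matching.*  The deeper library is binomially thinned so both
   replicates have the same expected total count.  (Read-level
   subsampling happens upstream of this package; count-level thinning
   is the in-scope equivalent.)
2. *Coverage binning.*  Bin boundaries are `⌈b^k⌉`, `k = 0, 1, 2, …`,
   with consecutive duplicates collapsed (for b near 1 the rounded
   powers repeat); gene `g` belongs to bin `i` when its mean coverage
   `(C_1g + C_2g)/2` lies in `(C̄_{i−1}, C̄_i]` (upper-inclusive).  The
   bin center is the geometric mean `Ĉ_i = sqrt(C̄_{i−1} C̄_i)`.
3. *Mixture fit.*  Within each retained bin, pooled AI values
   (two replicates summed) are converted to integer observations
   `x = round(AI · 2Ĉ)` on support `2Ĉ` and fitted with
   `ω₁ BetaBin(2Ĉ, α₁, α₁) + ω₂ BetaBin(2Ĉ, α₂, α₂)`, `ω₁ + ω₂ = 1`,
   `α₁ > 1` (narrow, near-balanced bulk), `α₂ ∈ (0, 1)` (wide,
   imbalanced tail), by EM from initials `ω₁ = 0.5, α₁ = 10,
   α₂ = 1/50`.
4. *Expected ΔAI.*  Per bin, 5000 true proportions are drawn from the
   fitted Beta mixture and resampled twice through
   `Binomial(Ĉ, p)/Ĉ`; quantiles of the absolute simulated
   differences give the binomial-noise expectation.
5. *Quantile ratios.*  Observed |ΔAI| quantiles at levels
   {0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.95} are divided by their
   expected counterparts per bin; the unweighted mean over all retained
   (bin, level) pairs — the least-squares constant fit — is the QCC.
   Quantiles are taken on absolute differences: the lower levels of the
   set would be non-positive on signed symmetric differences and their
   ratios ill-defined.
6. *Multiple replicates.*  Point estimates use all replicates pooled;
   the correction uses the arithmetic mean of all pairwise QCCs, with
   ratio-wise outlier flagging (default factor 1.5 from the median) to
   help identify aberrant replicates.

### Corrected inference

Observed AI is treated as a proportion measured with `QCC²` times fewer
reads.  One- and two-sample proportion tests (Yates-corrected
chi-square score statistic; Wilson score interval, with the continuity
correction clamped to the null deviation) are evaluated directly on
the real-valued scaled counts `(M/QCC², C/QCC²)` — both formulas are
algebraically well-defined off the integers, which is why the
proportion test is used rather than an exact binomial test.  At
QCC = 1 the corrected test is bit-identical to the standard one.
Point-AI tests accept a scalar or per-gene null (default 0.5) and
apply Bonferroni correction over all genes passing the coverage filter
(Benjamini-Hochberg and uncorrected thresholds are available but not
default).  Differential tests scale each sample by its own QCC and are
symmetric in sample order; an optional minimal |ΔAI| effect filter can
be stacked on significance.

## EM details

The weight update is the standard responsibility average.  The shape
update exploits symmetry: with the mean fixed at `Ĉ`, matching the
responsibility-weighted second moment `Σ_k` around `Ĉ` to the
beta-binomial variance gives the closed form
`α = ((2Ĉ)² − 4Σ) / (8Σ − 4Ĉ)`.  This moment step is not an exact
maximizer of the EM surrogate, and applied blindly it produces small
transient decreases of the log-likelihood.  The implementation
therefore evaluates the moment candidate first and accepts it whenever
the observed log-likelihood does not decrease (the overwhelming
majority of iterations); otherwise the shape update falls back to
bounded 1-D maximization of the expected complete-data log-likelihood,
restoring the EM ascent guarantee.  Numerical choices:

- constraints enforced by clamping: `α₁ ∈ (1+1e−6, 1e6]`,
  `α₂ ∈ [1e−6, 1−1e−6]`; a fit with `α₁` at its cap is flagged
  degenerate (zero-variance narrow component, e.g. all AI = 0.5);
- convergence when the largest parameter change falls below `1e−6`
  (default) or after 10,000 iterations, with a secondary stop when the
  log-likelihood change is below `1e−12` relative (parameters pinned
  at bounds can dither below that resolution indefinitely);
- beta-binomial log-pmfs are computed in log space from `gammaln` /
  `betaln` and evaluated once per unique count value per iteration
  (counts within a bin collapse to few distinct values).

Bins are retained for fitting and quantile comparison when at least 40
genes remain after requiring pooled coverage ≥ `min_fit_coverage`
(default 50, suitable for F1-hybrid mouse data; ~30 suits typical
human heterozygosity).  (Bin, level) pairs with a zero expected
quantile are dropped from the ratio fit; an estimate is refused when
fewer than 5 ratios remain.

## Synthetic data generator

The generator emulates the study conditions under which the method is
meant to operate, and doubles as the ground-truth source for the test
suite:

- *True AI*: a symmetric Beta (or Beta-mixture) draw parametrized by
  the intra-class correlation `ρ = 1/(2α+1)`; `ρ = 0` is the point
  mass at 0.5.  The default is a two-component mixture with weights
  (0.7, 0.3) and shapes (10, 0.2) — a near-balanced bulk plus a wide
  imbalanced tail, the shape the per-bin mixture fit recovers from
  tissue data.
- *Coverage*: log-uniform on [10, 10,000] by default (spanning the
  allelic-coverage range of deep bulk RNA-seq and populating every
  coverage bin), or constant; drawn once per gene and shared by all
  replicates, so replicates are depth-matched by construction.
- *Counts*: maternal counts are `Binomial(C_g, p)` with `p` equal to
  the true AI (inflation `k = 1`), or drawn per replicate from a Beta
  centered on the true AI with variance
  `v = (k² − 1) p(1−p) / (C − 1)`, the closed form that makes
  `sd(ΔAI)` exactly `k` times the binomial value — i.e. the generated
  pair has known target QCC `k`.  The calibration is unit-tested
  against the empirical `sd(ΔAI)`.

What the generator does *not* emulate: reference-mapping bias,
SNP-to-gene aggregation artifacts (counts are generated at gene level),
non-uniform overdispersion across the transcriptome, and
replicate-specific library sizes beyond thinning.  Passing tests
demonstrate calibration and recovery under these controlled conditions,
not the correctness of upstream allele counting on real alignments.

The single-library identifiability demonstration conflates a signal
Beta draw with beta-binomial technical noise: true AI from
`Beta(α_s, α_s)`, an observed proportion from a Beta centered on the
true AI with intra-class correlation `ρ_noise`, then a binomial count
at the given coverage.  How noise enters at a given coverage is an
interpretation (the composition above is the natural one); the
demonstration — that opposite signal/noise splits are indistinguishable
by KS and MWW tests at n = 500,000 and coverage 100 — is robust to it.

## Abundance overdispersion (auxiliary)

Extra-Poisson dispersion of total (non-allelic) counts across
replicates is summarized as `exp(intercept)` of a log-log regression
of dispersion (variance/mean) on mean expression.  Per-gene dispersion
estimates at few replicates are heavily skewed, so genes are first
grouped into geometric bins of the mean and the dispersion is averaged
within bins before taking logs (removing the Jensen bias that would
make even Poisson data appear underdispersed); the regression weights
bins by occupancy because sparse edge bins are the noisiest and sit
closest to the mean = 1 intercept.  Dividing dispersions by QCC²
before the fit checks whether the AI-derived correction also accounts
for the abundance overdispersion.

## Problem sizes and determinism

Simulation-based checks in the test suite use 2,000–10,000 genes per
run (constant coverage 100 for the repeated false-positive runs, the
log-uniform default elsewhere) and 5000-gene expected-ΔAI simulations —
sizes at which the pipeline's Monte-Carlo spread is well inside the
asserted tolerances.  Every stochastic step takes an explicit seed
(numpy `default_rng`); the QCC estimate varies by a few parts per
thousand with the seed of the expected-ΔAI simulation.

## Known limitations

- QCC calibrates *technical* noise; applied to biological replicates
  it absorbs genuine biological variation into the correction and
  cannot separate the two.
- The correction assumes overdispersion uniform across genes at a
  given coverage; gene-specific technical artifacts are not captured.
- Gene-level only: SNP-level overdispersion exists but the pipeline
  operates on aggregated gene counts.
- Count-level binomial thinning stands in for read-level subsampling
  when depth-matching replicates; the equivalence is an approximation.
- With a single coverage bin (constant-coverage data) the constant fit
  rests on 7 quantile ratios and is correspondingly noisier.
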