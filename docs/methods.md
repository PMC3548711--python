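# Methods

## The model

`aeusurv` detects two kinds of association between exon-level expression and
a continuous survival outcome, gene by gene. For a gene with exons
m = 1..M measured on patients n = 1..N, the log2 expression y_mn is modeled
as

    y_mn = μ + G_i + R_j + T_k + b·S_n + X_m + t_m·S_n + P_n + e_mn

with fixed effects for gender G, race R, therapy T and the survival
covariate S (months from diagnosis to death), and four independent
mean-zero Gaussian random effects:

| term | meaning | variance |
|------|---------|----------|
| X_m  | exon intercept deviation | σ²_exon (log2²) |
| t_m  | exon-specific survival-slope deviation | σ²_slope ((log2/month)²) |
| P_n  | patient effect | σ²_patient (log2²) |
| e_mn | residual | σ²_resid (log2²) |

The model is hierarchical in two ways: a population-level survival slope b
with exon-level deviations t_m, and a population-level expression level
with patient-level deviations P_n. Three nested specifications cover the
three gene classes:

1. **Full model** (all four random effects): multi-exon genes that may show
   alternative exon usage (AEU). A non-zero σ²_slope means the
   expression–survival association differs between exons — the statistical
   signature of AEU.
2. **Exon-common model** (drop t_m): multi-exon genes with one shared
   survival association.
3. **Single-exon model** (drop X_m and t_m): with one observation per
   patient the patient effect and residual are not separately identifiable,
   so the fit is ordinary least squares with the residual absorbing P_n.

Reference levels for the categorical fixed effects are female, other-race
and NONE therapy; the therapy factor has levels NONE/CRT/CRnT/OTHER/R. The
survival covariate is not centered by default (a config flag centers it,
which changes only the meaning of μ). A covariate level absent from the
cohort is dropped globally from the fixed design with a warning, so all
genes share an identical full-rank design.

## Estimation

Variance components are estimated by REML. The residual variance is
profiled out analytically; the remaining components are parameterized as
ratios γ_r = σ²_r/σ²_resid and optimized by bound-constrained L-BFGS-B
(bounds [0, 1e8]) using the analytic gradient of the profiled restricted
deviance, followed by a projected-Newton polish (Hessian by forward
differences of the gradient) that sharpens interior optima to ~1e-11 in
the gradient. Bounds rather than a log-variance transform are used so
that the optimizer can land exactly on the γ = 0 boundary, which the
boundary likelihood-ratio test and the "all slopes equal b when
σ²_slope = 0" identity require. Multi-start: γ = 1 and γ = 0.1 for all
components, plus (for the full model) the reduced-model optimum with
γ_slope = 0, which guarantees the likelihood-ratio statistic is
non-negative up to round-off.

All per-iteration linear algebra works on q×q cross-product matrices via
the Woodbury identity (q = 2M + N random-effect levels), never on the
(MN)×(MN) marginal covariance, so a 250-patient × 10-exon gene fits in
well under a second. Fixed effects are GLS at the estimated components;
BLUPs of the random effects and their prediction variances come from the
mixed-model equations, whose inverse also supplies cov(b̂, t̂_m) for the
per-exon slope standard errors. Components estimated on the boundary get
BLUP = 0 with zero prediction variance.

## Tests

* **AEU test** (H0: σ²_slope = 0): REML likelihood-ratio statistic
  q = 2(ℓ_full − ℓ_reduced), clipped at 0, referred to the 50:50
  chi-bar-square mixture of a point mass at zero and χ²₁ — the boundary
  reference for a single variance component; p = 1 when q = 0, else
  0.5·Pr(χ²₁ ≥ q). A Wald alternative (Z = σ̂²_slope/SE from the observed
  information, one-sided normal) is available by configuration; the LRT is
  the default. The mixture reference is mildly conservative at finite exon
  counts; the calibration benchmark measures this directly.
* **Survival test** (H0: b = 0): Wald t with residual degrees of freedom
  N_obs − rank(X). At the cohort sizes this package targets the normal
  limit dominates, so no Satterthwaite correction is attempted.
* **Per-exon slopes**: slope_m = b̂ + t̂_m with SE from
  var(b̂) + predvar(t̂_m) + 2cov, two-sided normal p, and fold change per
  additional survival month 2^slope_m.

## Calling the three groups

Per-gene p-values are BH-FDR adjusted in two separate families: multi-exon
AEU p-values (and multi-exon survival p-values), and single-exon survival
p-values — the single-exon model has different parameters, so mixing
families would distort both adjustments. Defaults: significance at
unadjusted p < 5.0e-4 or FDR < 0.05 (multi-exon), FDR < 0.1 (single-exon).

A multi-exon gene is **group 1** (AEU) when three criteria coincide:
(a) the AEU test is significant; (b) more than two (≥ 3) consecutive exons
are consistently over- or under-expressed; (c) those exons' fold changes
per month all fall outside [0.995, 1.005]. Criteria b and c are evaluated
jointly as the longest run of consecutive exons beyond the fold-change
band; the run is evaluated on the raw per-exon fold changes, with a
10-exon centered moving-average trend (truncated at gene ends; even
windows extend one position right) reported alongside for visual
inspection — the trend facilitates inspection but carries no numeric rule,
since any such rule would be an invention. A multi-exon gene failing the
AEU criteria but with a significant overall survival slope (taken from the
exon-common fit, which is the model that pairs with that hypothesis) is
**group 2**; a significant single-exon gene is **group 3**; everything
else is unlabelled. All thresholds, the run length, the fold-change band
and the window are configurable; setting min_run = 1 with band (1, 1)
degenerates the call to the significance criterion alone.

## Validation

Cross-cohort assessment is two-stage: training fixed effects plus exon
BLUPs predict validation expression (patient effects excluded — a new
patient's effect has expectation zero), scored by R² = 1 − SS_res/SS_tot.
Negative validation R² is possible and reported as-is with a flag. Because
it is ambiguous whether a validation R² should use training predictions or
a validation refit, both numbers are emitted (`r2_valid`,
`r2_valid_refit`). Per-exon slope agreement between independently fitted
cohorts is summarized by Pearson and Spearman correlations (undefined, and
reported missing, below 3 exons), with cohort-level medians aggregated
across genes. The validation refit reuses the specification chosen in
training; no re-selection.

## Enrichment

Two formula-level statistics summarize gene lists (web-service pipelines
around them are out of scope):

* **Overrepresentation**: upper-tail hypergeometric p of the overlap
  between the group-1 list and each gene set, background = all genes with
  a converged fit (not the full platform — logged explicitly), BH-FDR
  across sets.
* **Sign-partition log-odds**: every fitted gene is standardized by
  b̂/SE(b̂) and partitioned by sign; per set the 2×2 table
  (positive/negative × in/out) gives a natural-log odds ratio with the
  Haldane–Anscombe 0.5 correction when a cell is empty, and a two-sided
  Fisher exact p. Fisher's exact test is the package's choice of exact
  test for this layout. Negative log-odds ⇔ the set is more enriched among
  negatively associated genes. Genes with slope exactly 0 are excluded
  with a warning.

## Normalization

Probe-level intensities are log2 transformed (if raw), quantile normalized
(each column's sorted values replaced by the row-wise mean of all columns'
sorted values — idempotent, rank-preserving), and collapsed one exon at a
time with a one-step Tukey biweight: center at the median, scale
c·MAD + eps with c = 5 and eps = 1e-4 (the standard exon-array
summarization constants; exposed as arguments), redescending weights
(1 − u²)² inside |u| < 1 and zero outside. With MAD = 0 the median is
returned, since the weights are otherwise undefined. The one-step (not
iterated) estimator is used. Genes whose annotation mixes strands are
reduced to the strand carrying more exons before modeling (a tie keeps
"+" and warns — deterministic and, in practice, rare); exon order is the
ascending-genomic-start rank, re-ranked contiguously after filtering.
Coordinates are 0-based half-open.

## The synthetic-study generator

The generator draws data from exactly the model above, so the estimation
machinery can be tested against known truth. Its defaults emulate the
targeted study design: 250 training / 78 validation patients; male 62.4%,
caucasian 88.8%; therapy R 25.2%, CRT 10.8%, CRnT 39.6%, OTHER 14.0%,
NONE 10.4%; survival log-normal around the cohort medians (17.46 and
15.02 months) truncated to the observed ranges (0.16–128 and 0.10–77.57
months). The log-scale SD defaults to 1.0 — only the median and range are
observed, and σ_ln = 1 puts ~2% of draws above the training upper bound
before truncation, a plausible heavy-tailed survival profile. An
exponential-like alternative can be had by raising σ_ln. Survival is a
fully observed covariate; no censoring is simulated, matching the model's
treatment of survival as a regressor.

Gene sizes default to the observed mixture (11.2% single-exon, 79.9% with
2–24 exons, 7.7% with 25–49, 1.2% with ≥ 50, uniform within bins, max
191). Baseline expression μ = 7.0 log2 units with modest fixed effects
(male +0.10, caucasian −0.05, therapy +0.05..+0.20) — typical log2
intensity shifts; variance components default to 0.25 each. AEU genes
carry a cassette: a constant slope deviation (default 0.02 log2/month ≈
1.4%/month) over ≥ 3 consecutive exons, zero elsewhere; exon-common and
single-exon genes carry an overall slope of 0.01 log2/month. Each gene
draws from an RNG stream keyed by (seed, gene id), so simulation is
order-independent and reproducible; exon-level truth is shared between
cohorts while patient effects and residuals are cohort-specific. A
configurable minority-strand fraction (default 0) adds noise-only decoy
exons on the opposite strand to exercise the strand filter.

What the generator does *not* emulate: probe-level artifacts, spatial or
batch effects, genomic-distance-dependent covariance between exons,
censoring, and non-Gaussian expression. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness to real-array artifacts.

## Benchmark conditions and numerical choices

The reference benchmark sizes (in `aeusurv.evaluation`, used by the test
suite and `scripts/acceptance.py`) are: 2000 null genes at 50 patients ×
8 exons for LRT calibration; 50 replicates at 200 patients × 20 exons
(b = 0.01, σ²_slope = 1e-4, other components 0.25) for parameter
recovery; 20 random instances of ≤ 30 observations for the dense-oracle
likelihood check; and a 250-patient roster of 30 cassette + 30
exon-common + 20 single-exon + 120 null genes for caller operating
characteristics.

Numerical details: variance ratios below 1e-10 are snapped to the
boundary; optimizer stops at ftol 1e-14 / gtol 1e-11 plus the Newton
polish; a full-model likelihood below the reduced one beyond 1e-6 warns
and clips the LRT at 0; fits that fail (singular design, no residual df)
or do not converge exclude the gene with a logged reason. Reported
p-values use 4 significant digits and fold changes 4 decimals in the TSV
outputs.

## Known limitations

* The Wald variance-component test uses a finite-difference observed
  information; at or near the boundary its SE is undefined (reported NaN)
  — the LRT default is preferred.
* Residual-df t reference for the survival test is approximate in small
  cohorts; the package targets cohorts of tens to hundreds of patients.
* The moving-average trend is descriptive only.
* Exon–exon covariance beyond the shared patient effect (e.g. decaying
  with genomic distance) is not modeled.
* Sense–antisense (two-strand) modeling is out of scope; minority-strand
  exons are filtered, not modeled.
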