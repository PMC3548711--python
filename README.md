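# aeusurv

Gene-centric hierarchical mixed models for detecting **alternative exon
usage (AEU)** and exon-independent gene expression associated with a
continuous survival outcome, from exon-array (or any exon-level)
expression data. Built for transcriptomics analysts working with cohorts
such as glioblastoma patients, where survival in months is the phenotype
and expression is measured per exon on hundreds of patients.

## The model

For each gene with exons m = 1..M and patients n = 1..N, log2 expression
is modeled as

    y_mn = μ + G_i + R_j + T_k + b·S_n + X_m + t_m·S_n + P_n + e_mn

with fixed effects gender G, race R, therapy T and survival S (months),
and independent Gaussian random effects: exon intercepts
X_m ~ N(0, σ²_exon), exon-specific survival-slope deviations
t_m ~ N(0, σ²_slope), patient effects P_n ~ N(0, σ²_patient) and residual
e ~ N(0, σ²_resid). A significant σ²_slope means the expression–survival
association differs between the exons of the gene — the signature of AEU.
Three nested specifications (full; without t_m; single-exon OLS) cover
the three gene classes.

Estimation is REML (profiled residual variance, analytic gradients,
non-negativity bounds so boundary estimates are exact). The AEU test is a
boundary likelihood-ratio test against the 50:50 chi-bar-square mixture
½χ²₀ + ½χ²₁; the overall survival slope gets a Wald t test. A gene is
called **group 1** (AEU) when the test is significant (p < 5.0e-4 or
FDR < 0.05) *and* more than two consecutive exons have per-month fold
changes 2^slope outside [0.995, 1.005]; **group 2** is a significant
shared slope without AEU; **group 3** is a significant single-exon gene
(its own FDR family, cut at 0.1). Validation scoring (cross-cohort R²
and slope correlations) and enrichment statistics (hypergeometric
overrepresentation; sign-partition log-odds with Fisher exact p) complete
the pipeline. See `docs/methods.md` for the full account.

## Worked example

Everything can be exercised without external data via the synthetic-study
generator, which draws cohorts at the targeted study's covariate
frequencies (250/78 patients, 62.4% male, survival log-normal around a
17.46-month median) and expression from the model above with known truth:

```sh
aeusurv simulate --out-dir sim --seed 7 --n-aeu 3 --n-exon-common 3 \
    --n-single 2 --n-null 4 --n-train 120 --n-valid 40
aeusurv fit --expression sim/train_expression.tsv \
    --clinical sim/train_clinical.tsv --annotation sim/annotation.tsv \
    --out-dir res
```

prints

```
wrote synthetic study (12 genes) to sim
fitted 12 genes (0 excluded); group counts: {'none': 4, '1': 3, '2': 3, '3': 2}
```

— every planted gene is recovered in its true group and the four null
genes stay uncalled. `res/aeu_calls.tsv` holds one row per gene:

```
gene_id   n_exons  group  p_aeu      fdr_aeu    p_survival  ...  run_start  run_length
aeu0000   10       1      3.046e-49  1.015e-48  0.005032    ...  6          3
aeu0001   10       1      1.016e-50  5.082e-50  0.0002086   ...  2          3
```

`aeu0000` was simulated with a 3-exon cassette starting at exon 6 whose
inclusion rises ~1.4% per survival month; the call reports exactly that
run. `res/exon_slopes.tsv` gives the per-exon picture — background exons
sit at fold change ≈ 1.000 while the cassette exons stand out:

```
gene_id  exon_id      order  slope      se        p_exon     fold_change
aeu0000  aeu0000_e5   5      -0.001750  0.002564  0.49       0.9988
aeu0000  aeu0000_e6   6       0.020061  0.002564  5.2e-15    1.0140
aeu0000  aeu0000_e7   7       0.019507  0.002564  2.8e-14    1.0136
```

`aeusurv validate` refits a second cohort and reports cross-cohort R² and
slope correlations; `aeusurv enrich` takes a GMT file and emits both
enrichment tables; `aeusurv normalize` handles probe-level input (log2 →
quantile normalization → Tukey-biweight collapse to exons). The same
functionality is available as a library (`aeusurv.model.fit_reml`,
`aeusurv.caller.classify_genes`, ...).

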