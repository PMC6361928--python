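# gweis

Genome-wide by environment interaction (GWEIS) analysis for quantitative
traits: robust per-SNP SNP×exposure testing, GxE-weighted polygenic risk
scores, and incremental-prediction evaluation — with a synthetic-cohort
generator so the entire pipeline runs end-to-end without restricted data.

## Who this is for

Statistical geneticists studying how an environmental exposure — the
motivating case is counts of recent stressful life events (SLE) and their
effect on depressive-symptom scores — modifies per-SNP genetic effects.
Individual-level cohort genotypes are access-restricted, so the package
ships a first-class simulator that reproduces the statistical structure of
such a study (Hardy–Weinberg genotypes with local LD, a count-valued and
optionally heritable exposure, covariates, and a phenotype with additive,
interaction and heteroscedastic-noise components).

## The model

For each SNP *G* the full interaction model is fitted by OLS:

    Y = β₀ + β_G·G + β_E·E + β_GxE·(G×E) + β_C·C + ε

Because residual variance often differs across exposure levels (and plain
OLS interaction tests then over-reject), inference uses the Huber–White
sandwich covariance

    V = (XᵀX)⁻¹ Xᵀ diag(e²) X (XᵀX)⁻¹        (HC0; HC1 optional)

Two tests are reported per SNP: the 1-df Wald test of β_GxE (the *GxE
effect*) and the 2-df Wald test of (β_G, β_GxE) against both being zero
(the *joint effect* — the combined additive-main and interaction signal).

Summary statistics feed PRSice-style polygenic risk scores under three
weighting schemes — additive (PRS_D), interaction (PRS_GxE) and joint
(PRS_Joint, weight β_G + β_GxE ranked by the joint p) — after greedy LD
clumping (r² ≥ 0.1 within 250 kb by default) and p-value thresholding.
Nested regression models quantify what each score adds: incremental R²
beyond covariates, likelihood-ratio tests, permutation empirical p-values
((k+1)/(N+1)), and Benjamini–Hochberg FDR across a family of traits.

## Worked example

The packaged demo simulates a 2,000-sample × 5,000-SNP cohort (additive
heritability 10%, pure-interaction variance 5%, SLE-like exposure
averaging two events), splits it into discovery and target halves, runs
GWAS + GWEIS on discovery, builds the three scores, and evaluates them on
the target half:

```bash
gweis pipeline --config examples/demo.yaml --out-dir demo_out
```

The run prints genomic-inflation diagnostics and writes
`demo_out/demo.comparisons.csv`; with the packaged seed (1) it contains:

```
                 trait terms_null    terms_full  r2_null  r2_full  improvement_pct    lrt_p
combined_over_additive      PRS_D PRS_D+PRS_GxE 0.009645 0.011569          19.9447 0.159389
     joint_vs_combined  PRS_joint PRS_D+PRS_GxE 0.002887 0.011925         313.0400 0.002327
```

Reading the two rows: adding the GxE-weighted score to the additive score
raises the variance explained net of covariates from 0.96% to 1.16% (a
~20% relative gain — at this cohort size the LRT is only suggestive,
mirroring how weak cross-sample GxE transfer is in practice); and the
single joint-weighted score explains far less (0.29%) than modelling the
additive and interaction scores separately (1.19%, nested LRT
p = 2.3×10⁻³) — the demonstration that additive and GxE effects should
enter polygenic models as separate terms.

Every stage is also exposed individually (`gweis simulate | gwas | gweis |
prs-build | prs-score | evaluate`) on PLINK bed/bim/fam and FID/IID-keyed
tables, and as a Python API (`GweisScan`, `GwasScan`, `PrsScorer`,
`fit_comparison`, …) with scikit-learn estimator conventions.

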