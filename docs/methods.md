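# Methods

## Scope and model

The package implements a genome-wide by environment interaction (GWEIS)
workflow for a quantitative trait and a count-valued exposure. Per SNP it
fits, by ordinary least squares,

    Y = β₀ + β_G·G + β_E·E + β_GxE·(G×E) + covariates + ε,

and replaces the classical coefficient covariance with the Huber–White
sandwich estimator, `V = (X'X)⁻¹ X' diag(e²) X (X'X)⁻¹`. The default is
HC0 (the plain sandwich); HC1 (scaling by n/(n−k)) is available by flag.
Two Wald tests are derived from the robust covariance: a 1-df test of the
interaction coefficient, and a 2-df test of (β_G, β_GxE) jointly against
zero using the robust 2×2 block — the "joint effect" combining the
additive main and interaction signal at a SNP. The joint test is
implemented in Wald form; an asymptotically equivalent full-vs-null
comparison motivates it, and a robust-score variant is out of scope.
p-values use the normal (1-df) and χ²₂ reference distributions, which is
the asymptotic regime the sandwich estimator targets; −log₁₀ p columns are
reported alongside so that values below floating-point underflow remain
usable.

Modelling choices that were genuinely open:

- **Covariate×exposure interactions** are not fitted by default; the
  robust covariance absorbs the variance heterogeneity they induce. A
  flag (`add_covariate_interactions`) adds them for sensitivity analysis.
- **The exposure enters on its raw count scale** (the instrument scale,
  e.g. 0–12 life events), not standardised. The GxE p-value is invariant
  to affine rescaling of the exposure because the main-effect columns are
  refit per SNP; a test asserts this.
- **Missing dosages** are handled by per-SNP listwise deletion, with
  `n_used` recorded per SNP. Monomorphic SNPs and singular robust blocks
  are flagged by NaN statistics rather than dropped rows.
- **Genomic inflation** is summarised by the median-based λ and its
  quantitative-trait standardisation λ₁₀₀₀ = 1 + (λ−1)·1000/n.

## Synthetic cohorts

The generator (`gweis.simulate`) emulates the statistical structure the
analysis assumes; it is tested code, not a fixture.

- **Genotypes**: each SNP's effect-allele frequency is uniform on
  `maf_range` (default 0.05–0.5, common variants). Two latent standard-
  normal gametes per person are thresholded at the frequency quantile, so
  marginal Hardy–Weinberg holds exactly. Within blocks of
  `ld_block_size` (default 5) adjacent SNPs the latents follow an AR(1)
  correlation `ld_rho` (default 0.2, mild local LD). This is a one-
  parameter stand-in for real LD — sufficient for clumping and ranking
  logic, not for fine-mapping realism.
- **Exposure**: a Gaussian liability `√h²·score + √(1−h²)·noise` (score =
  standardised weighted sum over a random subset of `n_exposure_snps`
  SNPs, default 200) is quantile-mapped onto a Poisson(`exposure_mean`,
  default 2) count scale. `exposure_h2` (default 0) controls
  gene–environment correlation; 0.131 is the dependent-SLE setting used
  in tests, matching the heritability reported for behaviour-dependent
  life events. The monotone quantile transform slightly attenuates the
  R² of counts on the liability score (recovery tests use ±0.05
  tolerance).
- **Phenotype**: disjoint causal SNP sets get N(0,1) raw weights on
  standardised dosages, rescaled so the realised additive and interaction
  components match `var_additive` / `var_gxe` as fractions of total
  phenotypic variance (defaults 0.10 and 0.02, bracketing the 7–13%
  SNP-heritability range typical of depressive-symptom scores).
  Residuals are N(0, σ₀·(1 + hetero_factor·E)) — residual SD linear in
  the exposure, the pattern the robust test exists to handle. Covariates
  (age, sex) enter with fixed small effects (0.1 per standardised
  column). Genotypes are standardised before effects are applied so the
  variance fractions are interpretable; raw {0,1,2} dosages are what the
  PLINK writer emits.
- **Determinism**: every stage draws from `default_rng((seed, stage))`
  with a documented stage index, so outputs are bit-identical given a
  config and individually reproducible per stage.

No public effect-size distribution exists for life-event effects on
GHQ/PHQ-type scales; the defaults are realistic stand-ins, and passing
tests demonstrate correctness of the machinery under this generative
model — not calibration to any real cohort's LD, ascertainment or
measurement error.

## Questionnaire scales

Stressful-life-event instruments are decomposed as: TSLE = all "yes"
responses; DSLE = "yes" on behaviour-dependent items (items 6–11 of the
default 12-item classification); ISLE = "yes" on independent items (1–5)
with the pregnancy item removed; item 12 belongs to neither subscale.
The classification is configurable per instrument. The 28-item GHQ total
is transformed as ln(1 + Σ items) — the +1 offset keeps the all-zero
questionnaire finite, and the base is irrelevant to rank-based behaviour;
binary 0-0-1-1 scoring is available but not default. The PHQ recode is
the exact step function 0→0, 1–2→1, 3–5→2, ≥6→3. Missing item responses
count as "no" (0 for GHQ); callers needing another rule pre-impute.
Unaffected first-degree relatives of cases can be relabelled proxy cases
(self-reported case status takes precedence), which never shrinks the
analysis case group.

## Polygenic scores

Weights come from the scans under three schemes: additive (β from GWAS),
gxe (β_GxE ranked by the 1-df p), and joint (β_G + β_GxE ranked by the
2-df p — the natural per-allele combined effect at one exposure unit;
this interpretation of "joint weighting" is a documented design choice).
SNPs are pruned by greedy clumping — the most significant unclaimed SNP
claims neighbours within `window_kb` (250) whose dosage r² ≥ `clump_r2`
(0.1), PRSice-2 convention — with p-ties broken by (chromosome, position)
so results are independent of input row order. Scoring is the weighted
effect-allele dosage **sum** (PLINK `--score` sum convention); weights
are oriented to the panel's A1 coding, making scores exactly invariant to
swapping a weight row's effect allele with its sign; missing dosages are
imputed as 2 × the target panel's effect-allele frequency;
strand-ambiguous (A/T, C/G) SNPs can be dropped when matching external
weight tables. The best-fit threshold search uses the grid
{5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1}.

## Evaluation

Variance explained by PRS terms is always net of covariates: model R²
minus covariate-only R² (Nagelkerke pseudo-R² differences for binary
traits, the convention of the tooling this field uses; a liability-scale
alternative is out of scope). Nested models are compared by the LRT
2(ll_full − ll_null) on χ² with df = rank difference. Nesting is
validated by **column-span containment**, which accepts both name-subset
nesting and linear-constraint nesting. The latter matters for the
joint-vs-combined comparison: because scoring is linear, a joint-weighted
score built on a SNP set equals the sum of the additive- and
interaction-weighted scores on that same set, so "PRS_Joint vs
PRS_D + PRS_GxE" is an exact 1-df nested LRT when all three scores are
built on the joint-selected SNP set — this is how the pipeline implements
the comparison.

Permutation empirical p-values permute the phenotype against the intact
(PRS, covariates) design; a permutation counts when its model p for the
PRS term is at most the observed one (equivalently, absolute partial
correlation at least as large — same df, so the criteria coincide), and
the estimator is (1 + k)/(N_perm + 1), which cannot return zero. At
10,000 permutations the floor is 1/10,001 ≈ 9.999×10⁻⁵, reported as
< 1×10⁻⁴. BH step-up FDR is applied across the family of comparisons in
a report (family definition is the caller's choice of list).

## Numerical choices and problem sizes

Per-SNP fits solve the normal equations directly (design matrices have at
most a few dozen columns); the sandwich agrees with an explicit matrix
oracle and with statsmodels' HC0 to ~1e-14 relative error on shared
fixtures. p-values are floored at the smallest positive double; −log₁₀ p
comes from log-survival functions. The test suite and acceptance script
use cohorts of 2,000–6,000 samples and 300–5,000 SNPs with 5–20
replicates per stochastic check — sizes chosen so each statistical
property (type-I calibration within binomial bounds at 5,000 tests,
recovery bias within 2 SE over 400 causal-SNP estimates, majority-vote
model comparisons) is well-powered while the whole suite stays fast on a
single CPU.

## Known limitations

Binary-trait GWEIS (logistic), mixed-model association, meta-analysis,
imputation, realistic demography and LDpred-style continuous shrinkage
are out of scope. Cross-sample transfer of GxE-weighted scores is
intrinsically weak at these cohort sizes — the incremental-prediction
tests use concentrated interaction architectures to have reliable power,
and real-data gains of this kind are expected to be marginal.
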