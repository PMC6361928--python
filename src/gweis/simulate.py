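"""Synthetic cohorts with additive, GxE and gene-environment-correlation structure.

The generator emulates the statistical layout of a quantitative
depressive-symptom GWEIS: Hardy-Weinberg biallelic genotypes with
block-autoregressive LD, a count-valued stressful-life-event (SLE)
exposure that may be partly heritable, standard covariates, and a
phenotype built from the full interaction model

    Y = sum_j beta_G[j] G_std[j] + beta_E * E + sum_j beta_GxE[j] G_std[j] * E
        + covariate effects + eps,      eps ~ N(0, sigma0 * (1 + hetero_factor * E))

Genotypes are standardised (mean 0, variance 1 per SNP) before effects are
applied so that ``var_additive`` / ``var_gxe`` are interpretable variance
fractions; raw {0,1,2} dosages are what gets written to disk.

Reproducibility: every operation draws from ``numpy.random.default_rng``
seeded with ``(config.seed, stage)`` where stage is 0 for genotypes, 1 for
exposure, 2 for covariates and 3 for the phenotype, so stages are
individually and jointly deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel
from .plink import write_plink

_STAGE_GENOTYPES, _STAGE_EXPOSURE, _STAGE_COVARIATES, _STAGE_PHENOTYPE = range(4)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults describe the reference scenario used throughout the test
    suite: a cohort of 2,000 samples and 5,000 SNPs, common variants,
    SNP-heritability of 10% plus a 2% pure-interaction component, an SLE
    count averaging two events, and mild local LD.  ``exposure_h2``
    defaults to 0 (no gene-environment correlation); the dependent-SLE
    scenario uses 0.131.  Real effect-size distributions for SLE on
    depressive-symptom scales are not publicly established; these values
    are stand-ins chosen to be realistic for a quantitative-trait GWEIS.
    """

    n_samples: int = 2000
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_additive: int = 100
    n_causal_gxe: int = 100
    var_additive: float = 0.10
    var_gxe: float = 0.02
    beta_E: float = 0.2
    exposure_h2: float = 0.0
    exposure_mean: float = 2.0
    n_exposure_snps: int = 200
    hetero_factor: float = 0.0
    sigma0: float = 1.0
    ld_block_size: int = 5
    ld_rho: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.exposure_h2 < 1.0:
            raise ValueError(f"exposure_h2 must be in [0, 1), got {self.exposure_h2}")
        if self.var_additive + self.var_gxe >= 1.0:
            raise ValueError("var_additive + var_gxe must be < 1")
        if self.n_causal_additive + self.n_causal_gxe > self.n_snps:
            raise ValueError("more causal SNPs requested than n_snps")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.hetero_factor < 0:
            raise ValueError("hetero_factor must be >= 0")
        if self.n_samples < 2 or self.n_snps < 1:
            raise ValueError("need n_samples >= 2 and n_snps >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class ExposureTruth:
    """Exposure counts plus the generating genetic score (for recovery tests)."""

    counts: np.ndarray
    genetic_score: np.ndarray
    snp_indices: np.ndarray


@dataclass
class PhenotypeTruth:
    """Phenotype vector with the causal architecture that generated it."""

    y: np.ndarray
    causal_additive: np.ndarray
    beta_additive: np.ndarray  # per standardised dosage
    causal_gxe: np.ndarray
    beta_gxe: np.ndarray  # per standardised dosage x exposure unit
    beta_E: float
    sigma0: float
    components: dict = field(default_factory=dict)


def _standardize(mat: np.ndarray) -> np.ndarray:
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mat.mean(axis=0)) / sd


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw HWE genotypes with block-AR(1) LD via a latent-gamete model.

    Each SNP j has effect-allele frequency f_j ~ U(maf_range).  Within a
    block of ``ld_block_size`` adjacent SNPs, the two latent gametes per
    sample are multivariate normal with AR(1) correlation ``ld_rho``; an
    allele is present when its latent falls below the f_j quantile, so
    marginal HWE holds and adjacent SNPs show positive LD r^2.
    """
    rng = config.rng(_STAGE_GENOTYPES)
    n, m, b = config.n_samples, config.n_snps, max(1, config.ld_block_size)
    freqs = rng.uniform(*config.maf_range, size=m)

    dosages = np.empty((n, m))
    for start in range(0, m, b):
        width = min(b, m - start)
        if config.ld_rho > 0 and width > 1:
            corr = config.ld_rho ** np.abs(np.subtract.outer(np.arange(width), np.arange(width)))
            chol = np.linalg.cholesky(corr)
        else:
            chol = np.eye(width)
        latent = rng.standard_normal((n, 2, width)) @ chol.T
        thresh = stats.norm.ppf(freqs[start : start + width])
        dosages[:, start : start + width] = (latent < thresh).sum(axis=1)

    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": 5000 * np.arange(1, m + 1),
            "a1": "A",
            "a2": "C",
        }
    )
    return GenotypePanel(dosages, meta)


def simulate_exposure(panel: GenotypePanel, config: SimConfig) -> ExposureTruth:
    """Count-valued SLE exposure, optionally partly heritable.

    A Gaussian liability ``sqrt(h2) * score + sqrt(1 - h2) * noise`` (score
    = standardised weighted sum over a random SNP subset) is mapped through
    the monotone quantile transform ``Poisson(exposure_mean).ppf(Phi(.))``
    to non-negative integer counts.  With ``exposure_h2 = 0`` the counts
    are independent of genotype.
    """
    rng = config.rng(_STAGE_EXPOSURE)
    n = panel.n_samples
    k = min(config.n_exposure_snps, panel.n_snps)
    idx = rng.choice(panel.n_snps, size=k, replace=False)
    weights = rng.standard_normal(k)
    score = _standardize(panel.dosages[:, idx]) @ weights
    score = (score - score.mean()) / (score.std() or 1.0)

    noise = rng.standard_normal(n)
    h2 = config.exposure_h2
    liability = np.sqrt(h2) * score + np.sqrt(1.0 - h2) * noise
    counts = stats.poisson.ppf(stats.norm.cdf(liability), mu=config.exposure_mean)
    return ExposureTruth(counts=counts.astype(float), genetic_score=score, snp_indices=idx)


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Age + sex covariate table (the analysis treats covariates generically)."""
    rng = config.rng(_STAGE_COVARIATES)
    n = config.n_samples
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(50.0, 10.0, size=n), 1),
            "sex": rng.integers(0, 2, size=n).astype(float),
        }
    )


#: effect per standardised covariate column in `simulate_phenotype`
_COVARIATE_EFFECT = 0.1


def simulate_phenotype(
    panel: GenotypePanel,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None,
    config: SimConfig,
) -> PhenotypeTruth:
    """Quantitative phenotype from the full interaction model.

    Disjoint causal SNP sets receive N(0,1) raw weights which are then
    rescaled so the realised variance of the additive and interaction
    components match ``var_additive`` / ``var_gxe`` as fractions of the
    total phenotypic variance.  Residuals are heteroscedastic when
    ``hetero_factor > 0`` (SD linear in the exposure).
    """
    exposure = np.asarray(exposure, dtype=float)
    if exposure.shape[0] != panel.n_samples:
        raise ValueError(
            f"exposure has {exposure.shape[0]} entries for {panel.n_samples} samples"
        )
    if covariates is not None and len(covariates) != panel.n_samples:
        raise ValueError("covariate rows do not match sample count")

    rng = config.rng(_STAGE_PHENOTYPE)
    n = panel.n_samples
    order = rng.permutation(panel.n_snps)
    idx_add = np.sort(order[: config.n_causal_additive])
    idx_gxe = np.sort(order[config.n_causal_additive : config.n_causal_additive + config.n_causal_gxe])

    g_std_add = _standardize(panel.dosages[:, idx_add]) if idx_add.size else np.empty((n, 0))
    g_std_gxe = _standardize(panel.dosages[:, idx_gxe]) if idx_gxe.size else np.empty((n, 0))
    beta_add = rng.standard_normal(idx_add.size)
    beta_gxe = rng.standard_normal(idx_gxe.size)

    fixed = config.beta_E * exposure
    if covariates is not None and covariates.shape[1]:
        fixed = fixed + _standardize(covariates.to_numpy(float)) @ np.full(
            covariates.shape[1], _COVARIATE_EFFECT
        )
    eps = rng.standard_normal(n) * config.sigma0 * (1.0 + config.hetero_factor * exposure)

    # scale causal components so realised variance fractions hit the targets
    var_rest = np.var(fixed + eps)
    var_total = var_rest / (1.0 - config.var_additive - config.var_gxe)

    additive = g_std_add @ beta_add if idx_add.size else np.zeros(n)
    if config.var_additive > 0 and additive.std() > 0:
        scale = np.sqrt(config.var_additive * var_total / additive.var())
        additive, beta_add = additive * scale, beta_add * scale
    else:
        additive, beta_add = np.zeros(n), np.zeros(idx_add.size)

    interaction = (g_std_gxe * exposure[:, None]) @ beta_gxe if idx_gxe.size else np.zeros(n)
    if config.var_gxe > 0 and interaction.std() > 0:
        scale = np.sqrt(config.var_gxe * var_total / interaction.var())
        interaction, beta_gxe = interaction * scale, beta_gxe * scale
    else:
        interaction, beta_gxe = np.zeros(n), np.zeros(idx_gxe.size)

    y = additive + interaction + fixed + eps
    return PhenotypeTruth(
        y=y,
        causal_additive=idx_add,
        beta_additive=beta_add,
        causal_gxe=idx_gxe,
        beta_gxe=beta_gxe,
        beta_E=config.beta_E,
        sigma0=config.sigma0,
        components={"additive": additive, "interaction": interaction, "fixed": fixed, "eps": eps},
    )


def write_fixture(
    panel: GenotypePanel,
    exposure: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Emit bed/bim/fam plus FID/IID-keyed phenotype, covariate and exposure tables."""
    exposure = np.asarray(exposure, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if not (len(exposure) == len(phenotype) == panel.n_samples):
        raise ValueError("sample counts of panel, exposure and phenotype differ")
    out_prefix = Path(out_prefix)
    write_plink(panel, out_prefix)

    ids = pd.DataFrame(panel.sample_ids, columns=["FID", "IID"])
    paths: dict[str, Path] = {
        "bed": out_prefix.with_suffix(".bed"),
        "bim": out_prefix.with_suffix(".bim"),
        "fam": out_prefix.with_suffix(".fam"),
    }

    pheno = ids.assign(PHENO=phenotype)
    paths["phenotype"] = out_prefix.with_suffix(".pheno")
    pheno.to_csv(paths["phenotype"], sep="\t", index=False)

    expo = ids.assign(EXPOSURE=exposure)
    paths["exposure"] = out_prefix.with_suffix(".exposure")
    expo.to_csv(paths["exposure"], sep="\t", index=False)

    if covariates is not None:
        covar = pd.concat([ids, covariates.reset_index(drop=True)], axis=1)
        paths["covariate"] = out_prefix.with_suffix(".covar")
        covar.to_csv(paths["covariate"], sep="\t", index=False)
    return paths
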