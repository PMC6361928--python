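"""Per-SNP association scans: additive GWAS and robust GWEIS.

The GWEIS engine fits, per SNP, the full interaction model

    Y ~ b0 + b_G G + b_E E + b_GxE (G x E) + covariates

by ordinary least squares and replaces the classical coefficient
covariance with the Huber-White sandwich

    V = (X'X)^{-1} X' diag(e^2) X (X'X)^{-1}          (HC0; HC1 scales by n/(n-k))

so that inference stays calibrated when residual variance differs across
exposure levels.  Two tests are reported per SNP:

* the 1-df GxE Wald test,  z = b_GxE / se_GxE  (robust SE), and
* the 2-df joint Wald test on (b_G, b_GxE),  chi2 = b' S^{-1} b with S the
  robust 2x2 covariance block — the combined additive-main + interaction
  signal at the SNP.

Missing dosages are handled by per-SNP listwise deletion; ``n_used`` is
recorded per SNP.  The exposure enters on its raw count scale; GxE
p-values are invariant to affine rescaling of the exposure because the
main-effect columns are refit per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

_LOG10 = np.log(10.0)
#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

SUMSTAT_COLUMNS_GWEIS = [
    "SNP", "CHR", "BP", "A1", "A2", "N",
    "BETA_G", "SE_G", "BETA_E", "SE_E", "BETA_GXE", "SE_GXE",
    "P_GXE", "CHI2_JOINT", "P_JOINT",
]
SUMSTAT_COLUMNS_GWAS = ["SNP", "CHR", "BP", "A1", "A2", "N", "BETA", "SE", "P"]


def _as_covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    mat = np.asarray(
        covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else covariates,
        dtype=float,
    )
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] != n:
        raise ValueError(f"covariates have {mat.shape[0]} rows for {n} samples")
    return mat


def _check_full_rank(X: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{what} design matrix is rank deficient")


class GwasScan(BaseEstimator):
    """Additive per-SNP OLS scan (classical standard errors, t-based p).

    Parameters
    ----------
    standardize
        Regress on per-SNP standardised dosages instead of raw {0,1,2}.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, panel, y, covariates=None):
        y = np.asarray(y, dtype=float)
        n = panel.n_samples
        if y.shape[0] != n:
            raise ValueError("phenotype length does not match panel")
        C = _as_covariate_matrix(covariates, n)
        base = np.column_stack([np.ones(n), C])
        _check_full_rank(base, "covariate")
        k = base.shape[1] + 1

        freqs = panel.allele_frequency()
        rows = []
        for j in range(panel.n_snps):
            g = panel.dosages[:, j]
            mask = np.isfinite(g)
            gj, yj, Xb = g[mask], y[mask], base[mask]
            nj = int(mask.sum())
            if nj <= k or gj.std() == 0:
                rows.append((nj, np.nan, np.nan, np.nan))
                continue
            if self.standardize:
                gj = (gj - gj.mean()) / gj.std()
            X = np.column_stack([Xb, gj])
            XtX = X.T @ X
            beta = np.linalg.solve(XtX, X.T @ yj)
            resid = yj - X @ beta
            s2 = resid @ resid / (nj - k)
            se = np.sqrt(s2 * np.linalg.inv(XtX)[-1, -1])
            t = beta[-1] / se
            p = 2.0 * stats.t.sf(abs(t), df=nj - k)
            rows.append((nj, beta[-1], se, max(p, np.nextafter(0, 1))))

        meta = panel.snp_meta
        self.results_ = pd.DataFrame(
            {
                "SNP": meta["snp_id"].to_numpy(),
                "CHR": meta["chrom"].to_numpy(),
                "BP": meta["pos"].to_numpy(),
                "A1": meta["a1"].to_numpy(),
                "A2": meta["a2"].to_numpy(),
                "FREQ_A1": freqs,
                "N": [r[0] for r in rows],
                "BETA": [r[1] for r in rows],
                "SE": [r[2] for r in rows],
                "P": [r[3] for r in rows],
            }
        )
        return self


def _sandwich(X: np.ndarray, resid: np.ndarray, variant: str) -> np.ndarray:
    XtX_inv = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (resid ** 2)[:, None])
    V = XtX_inv @ meat @ XtX_inv
    if variant == "HC1":
        n, k = X.shape
        V = V * n / (n - k)
    elif variant != "HC0":
        raise ValueError(f"robust_variant must be HC0 or HC1, got {variant!r}")
    return V


class GweisScan(BaseEstimator):
    """Per-SNP interaction scan with Huber-White robust inference.

    Parameters
    ----------
    robust_variant
        "HC0" (plain sandwich, default) or "HC1" (n/(n-k) small-sample
        scaling).
    standardize
        Regress on standardised dosages (effects per SD of dosage).
    add_covariate_interactions
        Also fit covariate x exposure columns (sensitivity analysis; off
        by default — the robust covariance already absorbs the induced
        variance heterogeneity).
    classical_se
        Additionally report non-robust (model-based) SE and p for the GxE
        term, for calibration diagnostics.
    """

    def __init__(
        self,
        robust_variant: str = "HC0",
        standardize: bool = False,
        add_covariate_interactions: bool = False,
        classical_se: bool = False,
    ):
        self.robust_variant = robust_variant
        self.standardize = standardize
        self.add_covariate_interactions = add_covariate_interactions
        self.classical_se = classical_se

    def fit(self, panel, y, exposure, covariates=None):
        y = np.asarray(y, dtype=float)
        e = np.asarray(exposure, dtype=float)
        n = panel.n_samples
        if y.shape[0] != n or e.shape[0] != n:
            raise ValueError("phenotype/exposure length does not match panel")
        if np.std(e) == 0:
            raise ValueError(
                "exposure is constant across samples: G and GxE columns are collinear"
            )
        C = _as_covariate_matrix(covariates, n)
        if self.add_covariate_interactions and C.shape[1]:
            C = np.column_stack([C, C * e[:, None]])
        base = np.column_stack([np.ones(n), C, e])
        _check_full_rank(base, "covariate/exposure")
        e_col = base.shape[1] - 1
        k = base.shape[1] + 2  # + G + GxE

        freqs = panel.allele_frequency()
        m = panel.n_snps
        out = {
            name: np.full(m, np.nan)
            for name in (
                "BETA_G", "SE_G", "BETA_E", "SE_E", "BETA_GXE", "SE_GXE",
                "P_GXE", "NEG_LOG10_P_GXE", "CHI2_JOINT", "P_JOINT",
                "NEG_LOG10_P_JOINT", "SE_GXE_CLASSICAL", "P_GXE_CLASSICAL",
            )
        }
        n_used = np.zeros(m, dtype=int)

        for j in range(m):
            g = panel.dosages[:, j]
            mask = np.isfinite(g)
            gj, yj, ej, Xb = g[mask], y[mask], e[mask], base[mask]
            nj = int(mask.sum())
            n_used[j] = nj
            if nj <= k + 5 or gj.std() == 0:
                continue  # monomorphic or underpowered: flagged by NaN stats
            if self.standardize:
                gj = (gj - gj.mean()) / gj.std()
            X = np.column_stack([Xb, gj, gj * ej])
            XtX = X.T @ X
            try:
                beta = np.linalg.solve(XtX, X.T @ yj)
            except np.linalg.LinAlgError:
                continue
            resid = yj - X @ beta
            V = _sandwich(X, resid, self.robust_variant)

            ig, igxe = X.shape[1] - 2, X.shape[1] - 1
            se = np.sqrt(np.diag(V))
            out["BETA_G"][j], out["SE_G"][j] = beta[ig], se[ig]
            out["BETA_E"][j], out["SE_E"][j] = beta[e_col], se[e_col]
            out["BETA_GXE"][j], out["SE_GXE"][j] = beta[igxe], se[igxe]

            z = beta[igxe] / se[igxe]
            logsf = stats.norm.logsf(abs(z))
            out["P_GXE"][j] = max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1))
            out["NEG_LOG10_P_GXE"][j] = -(np.log(2.0) + logsf) / _LOG10

            S = V[np.ix_((ig, igxe), (ig, igxe))]
            b = beta[[ig, igxe]]
            try:
                chi2 = float(b @ np.linalg.solve(S, b))
            except np.linalg.LinAlgError:
                continue  # singular robust block: joint test flagged by NaN
            out["CHI2_JOINT"][j] = chi2
            out["P_JOINT"][j] = max(stats.chi2.sf(chi2, 2), np.nextafter(0, 1))
            out["NEG_LOG10_P_JOINT"][j] = -stats.chi2.logsf(chi2, 2) / _LOG10

            if self.classical_se:
                s2 = resid @ resid / (nj - X.shape[1])
                se_c = np.sqrt(s2 * np.linalg.inv(XtX)[igxe, igxe])
                zc = beta[igxe] / se_c
                out["SE_GXE_CLASSICAL"][j] = se_c
                out["P_GXE_CLASSICAL"][j] = max(
                    2.0 * stats.norm.sf(abs(zc)), np.nextafter(0, 1)
                )

        meta = panel.snp_meta
        result = pd.DataFrame(
            {
                "SNP": meta["snp_id"].to_numpy(),
                "CHR": meta["chrom"].to_numpy(),
                "BP": meta["pos"].to_numpy(),
                "A1": meta["a1"].to_numpy(),
                "A2": meta["a2"].to_numpy(),
                "FREQ_A1": freqs,
                "N": n_used,
            }
        )
        for name, vals in out.items():
            result[name] = vals
        if not self.classical_se:
            result = result.drop(columns=["SE_GXE_CLASSICAL", "P_GXE_CLASSICAL"])
        self.results_ = result
        return self


def run_gwas(panel, y, covariates=None, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`GwasScan`."""
    return GwasScan(**kwargs).fit(panel, y, covariates).results_


def run_gweis(panel, y, exposure, covariates=None, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`GweisScan`."""
    return GweisScan(**kwargs).fit(panel, y, exposure, covariates).results_


@dataclass
class InflationReport:
    lambda_gc: float
    lambda_1000: float
    n_effective: int


def genomic_inflation(pvals, n: int) -> InflationReport:
    """Median-based genomic-control lambda and its n=1000 standardisation.

    lambda_gc = median(chi2_1.isf(p)) / 0.4549364; for a quantitative trait
    lambda_1000 = 1 + (lambda_gc - 1) * 1000 / n.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_1DF_MEDIAN)
    lam1000 = 1.0 + (lam - 1.0) * 1000.0 / n
    return InflationReport(lambda_gc=lam, lambda_1000=lam1000, n_effective=n)


def bonferroni_threshold(n_snps: int, n_tests_per_snp: int = 1, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / (n_snps * n_tests_per_snp)."""
    if n_snps < 1 or n_tests_per_snp < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_snps * n_tests_per_snp)
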