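"""Predictive evaluation of polygenic scores: nested models, permutation p, FDR.

Variance explained by PRS terms is always reported net of covariates:
for a quantitative trait it is model R^2 minus the covariate-only R^2;
for a binary trait the same difference on Nagelkerke's pseudo-R^2 scale.
Nested comparisons are tested with the likelihood-ratio test
LRT = 2 (ll_full - ll_null) ~ chi-square(df = parameter difference);
nesting is validated by column-span containment, which accepts both
name-subset nesting and linear-constraint nesting (e.g. a joint-weighted
score versus its additive and interaction components on the same SNP set).

Empirical significance follows the PRSice convention: the phenotype is
permuted against the intact (PRS, covariate) design and the empirical p
is (1 + #{permuted fit at least as good}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelComparison:
    """Nested-regression comparison of PRS predictor sets."""

    trait_id: str
    terms_null: list[str]
    terms_full: list[str]
    r2_null: float
    r2_full: float
    incremental_r2: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    n: int
    empirical_p: float | None = None
    fdr_p: float | None = None
    extras: dict = field(default_factory=dict)


def _design(covariates, n, *terms) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    for t in terms:
        t = np.asarray(t, dtype=float)
        cols.append(t[:, None] if t.ndim == 1 else t)
    return np.column_stack(cols)


def _spans(outer: np.ndarray, inner: np.ndarray, tol: float = 1e-8) -> bool:
    """True when every column of ``inner`` lies in the column span of ``outer``."""
    coef, *_ = np.linalg.lstsq(outer, inner, rcond=None)
    resid = inner - outer @ coef
    scale = np.linalg.norm(inner) or 1.0
    return np.linalg.norm(resid) / scale < tol


def _terms_matrix(terms: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, list[str]]:
    if terms is None:
        return np.empty((n, 0)), []
    if isinstance(terms, pd.DataFrame):
        return terms.to_numpy(float), list(terms.columns)
    arr = np.asarray(terms, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"term{i}" for i in range(arr.shape[1])]


def _ols_fit(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, X).fit()


def _logit_fit(X: np.ndarray, y: np.ndarray):
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        fit.separation_flag = True  # likely (quasi-)separation
    return fit


def _nagelkerke(ll_model: float, ll_intercept: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_intercept - ll_model) / n)
    return float(cox_snell / (1.0 - np.exp(2.0 * ll_intercept / n)))


def fit_comparison(
    phenotype,
    prs_terms_null,
    prs_terms_full,
    covariates=None,
    family: str = "gaussian",
    trait_id: str = "trait",
) -> ModelComparison:
    """Compare nested PRS predictor sets on top of shared covariates.

    ``prs_terms_null`` / ``prs_terms_full`` are DataFrames (or arrays) of
    PRS columns; the full set must contain the null set (by name or by
    column span).  R^2 values are the variance attributable to the PRS
    terms beyond covariates (Nagelkerke pseudo-R^2 for ``family=
    "binomial"``).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    null_mat, null_names = _terms_matrix(prs_terms_null, n)
    full_mat, full_names = _terms_matrix(prs_terms_full, n)

    X_cov = _design(covariates, n)
    X_null = _design(covariates, n, null_mat) if null_mat.shape[1] else X_cov
    X_full = _design(covariates, n, full_mat) if full_mat.shape[1] else X_cov
    name_nested = set(null_names) <= set(full_names)
    if not name_nested and not _spans(X_full, X_null):
        raise ValueError("full model does not nest the null model (name or span)")

    if family == "gaussian":
        fit_cov, fit_null, fit_full = (_ols_fit(X, y) for X in (X_cov, X_null, X_full))
        r2_null = fit_null.rsquared - fit_cov.rsquared
        r2_full = fit_full.rsquared - fit_cov.rsquared
    elif family == "binomial":
        uniq = np.unique(y)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("binomial family requires a 0/1 phenotype")
        fit_cov, fit_null, fit_full = (_logit_fit(X, y) for X in (X_cov, X_null, X_full))
        ll0 = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
        r2_null = _nagelkerke(fit_null.llf, ll0, n) - _nagelkerke(fit_cov.llf, ll0, n)
        r2_full = _nagelkerke(fit_full.llf, ll0, n) - _nagelkerke(fit_cov.llf, ll0, n)
    else:
        raise ValueError(f"family must be 'gaussian' or 'binomial', got {family!r}")

    df = int(np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_null))
    lrt = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    lrt_p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0

    return ModelComparison(
        trait_id=trait_id,
        terms_null=null_names,
        terms_full=full_names,
        r2_null=float(r2_null),
        r2_full=float(r2_full),
        incremental_r2=float(r2_full - r2_null),
        lrt_stat=float(lrt),
        lrt_df=df,
        lrt_p=lrt_p,
        n=n,
        extras={"separation": bool(getattr(fit_full, "separation_flag", False))},
    )


def incremental_r2(phenotype, prs, covariates=None) -> float:
    """OLS R^2 gained by adding one PRS term over covariates alone."""
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    X_cov = _design(covariates, n)
    X = _design(covariates, n, np.asarray(prs, dtype=float))
    return float(_ols_fit(X, y).rsquared - _ols_fit(X_cov, y).rsquared)


def permutation_empirical_p(
    phenotype,
    prs_term,
    covariates=None,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation empirical p for one PRS term over covariates.

    The phenotype is permuted ``n_perm`` times against the intact (PRS,
    covariates) design; a permutation counts when its model p for the PRS
    term is <= the observed one (equivalently, when the absolute partial
    correlation of permuted phenotype with the PRS given covariates is at
    least the observed).  Returns (1 + k) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("phenotype is constant")
    prs = np.asarray(prs_term, dtype=float)
    n = y.shape[0]

    X_cov = _design(covariates, n)
    Q, _ = np.linalg.qr(X_cov)
    q_prs = prs - Q @ (Q.T @ prs)
    norm = np.linalg.norm(q_prs)
    if norm == 0:
        raise ValueError("PRS term is collinear with covariates")
    q_prs = q_prs / norm

    def partial_abs_corr(yy: np.ndarray) -> np.ndarray:
        ry = yy - Q @ (Q.T @ yy)
        denom = np.linalg.norm(ry, axis=0)
        return np.abs(q_prs @ yy) / np.where(denom == 0, np.inf, denom)

    observed = float(partial_abs_corr(y[:, None])[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 500
    for start in range(0, n_perm, chunk):
        size = min(chunk, n_perm - start)
        perms = np.empty((n, size))
        for i in range(size):
            perms[:, i] = y[rng.permutation(n)]
        exceed += int((partial_abs_corr(perms) >= observed - 1e-15).sum())
    return (1 + exceed) / (n_perm + 1)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def improvement_report(comparisons: list[ModelComparison]) -> pd.DataFrame:
    """Tabulate per-comparison variance explained and % predictive improvement.

    improvement_pct = incremental_r2 / r2_null x 100 — the relative gain of
    the full PRS set over the null PRS set (both net of covariates).
    LRT p-values are FDR-adjusted across the supplied family of
    comparisons.
    """
    rows = []
    for c in comparisons:
        improvement = 100.0 * c.incremental_r2 / c.r2_null if c.r2_null > 0 else (
            0.0 if c.incremental_r2 == 0 else np.nan
        )
        rows.append(
            {
                "trait": c.trait_id,
                "terms_null": "+".join(c.terms_null) or "covariates",
                "terms_full": "+".join(c.terms_full),
                "r2_null": c.r2_null,
                "r2_full": c.r2_full,
                "incremental_r2": c.incremental_r2,
                "improvement_pct": improvement,
                "lrt_stat": c.lrt_stat,
                "lrt_df": c.lrt_df,
                "lrt_p": c.lrt_p,
                "empirical_p": c.empirical_p,
                "n": c.n,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_lrt_p"] = fdr_adjust(out["lrt_p"].to_numpy())
    emp = out["empirical_p"].to_numpy(dtype=float)
    if np.isfinite(emp).all():
        out["fdr_empirical_p"] = fdr_adjust(emp)
    return out


def plot_heatmap(report: pd.DataFrame, path, value: str = "r2_full") -> None:
    """Traits x predictor-set heatmap of variance explained (% scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = report.pivot_table(index="terms_full", columns="trait", values=value)
    fig, ax = plt.subplots(figsize=(1.2 + pivot.shape[1], 1.0 + 0.6 * pivot.shape[0]))
    im = ax.imshow(100.0 * pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{100 * pivot.iat[i, j]:.2f}", ha="center", va="center", color="w")
    fig.colorbar(im, label="% variance explained")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
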