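"""Polygenic risk scores from GWAS/GWEIS summary statistics.

Weights come in three schemes:

* ``additive`` — the GWAS main effect (PRS_D / PRS_MDD-style),
* ``gxe``      — the GWEIS interaction coefficient (PRS_GxE),
* ``joint``    — beta_G + beta_GxE ranked by the 2-df joint p (PRS_Joint);
  the sum is the per-allele combined effect at one exposure unit.

SNPs are pruned by greedy LD clumping (most significant SNP claims its
correlated neighbours) and selected by p-value thresholding before the
weighted allele-dosage sum is accumulated — the PRSice/PLINK ``--score``
convention (sum, not mean; missing dosages imputed as 2 x effect-allele
frequency of the target panel).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import GenotypePanel

#: PRSice-style default p-value threshold grid
DEFAULT_THRESHOLD_GRID = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

SCHEMES = ("additive", "gxe", "joint")


def clump(
    sumstats: pd.DataFrame,
    reference: GenotypePanel,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p1: float = 1.0,
    p_col: str = "P",
) -> list[str]:
    """Greedy LD clumping; returns retained index-SNP ids.

    Repeatedly takes the smallest-p unclaimed SNP with p <= ``p1`` as an
    index SNP and claims all unclaimed SNPs on the same chromosome within
    ``window_kb`` whose dosage correlation r^2 with it is >=
    ``r2_threshold``.  Ties in p are broken by (chromosome, position) so
    the result is independent of input row order.
    """
    meta = reference.snp_meta.set_index("snp_id")
    ss = sumstats[sumstats["SNP"].isin(meta.index)].copy()
    dropped = len(sumstats) - len(ss)
    if dropped:
        warnings.warn(f"{dropped} summary-statistic SNPs absent from reference; dropped")
    if ss.empty:
        raise ValueError("no summary-statistic SNPs overlap the reference panel")
    ss = ss.dropna(subset=[p_col])

    ss["chr_ref"] = meta.loc[ss["SNP"], "chrom"].to_numpy()
    ss["bp_ref"] = meta.loc[ss["SNP"], "pos"].to_numpy()
    ss = ss.sort_values([p_col, "chr_ref", "bp_ref"], kind="mergesort").reset_index(drop=True)

    col_of = {s: i for i, s in enumerate(reference.snp_meta["snp_id"])}
    snp_ids = ss["SNP"].to_numpy()
    pvals = ss[p_col].to_numpy()
    cols = np.array([col_of[s] for s in snp_ids])
    window_bp = window_kb * 1000.0
    # candidate neighbours looked up per chromosome in position order
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in ss.groupby("chr_ref", sort=False):
        order = np.argsort(grp["bp_ref"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (grp["bp_ref"].to_numpy()[order], grp.index.to_numpy()[order])

    claimed = np.zeros(len(ss), dtype=bool)
    retained: list[str] = []

    for i in range(len(ss)):
        if claimed[i] or pvals[i] > p1:
            continue
        retained.append(snp_ids[i])
        claimed[i] = True
        bps, ss_rows = by_chrom[ss.at[i, "chr_ref"]]
        bp_i = ss.at[i, "bp_ref"]
        lo, hi = np.searchsorted(bps, (bp_i - window_bp, bp_i + window_bp + 1))
        cand = ss_rows[lo:hi]
        cand = cand[~claimed[cand]]
        if cand.size == 0:
            continue
        g_index = reference.dosages[:, cols[i]]
        G = reference.dosages[:, cols[cand]]
        r2 = _pairwise_r2(g_index, G)
        claimed[cand[r2 >= r2_threshold]] = True
    return retained


def _pairwise_r2(g: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one dosage vector with each column of G."""
    out = np.zeros(G.shape[1])
    finite_g = np.isfinite(g)
    for j in range(G.shape[1]):
        mask = finite_g & np.isfinite(G[:, j])
        if mask.sum() < 3:
            continue
        x, y = g[mask], G[:, j][mask]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
        out[j] = r * r
    return out


def build_weights(records: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Weight table (SNP, A1, WEIGHT, P) from scan summary statistics."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    needed = {
        "additive": ["BETA", "P"],
        "gxe": ["BETA_GXE", "P_GXE"],
        "joint": ["BETA_G", "BETA_GXE", "P_JOINT"],
    }[scheme]
    missing = [c for c in needed + ["SNP", "A1"] if c not in records.columns]
    if missing:
        raise ValueError(f"scheme {scheme!r} needs columns {missing}")
    if scheme == "additive":
        weight, p = records["BETA"], records["P"]
    elif scheme == "gxe":
        weight, p = records["BETA_GXE"], records["P_GXE"]
    else:
        weight, p = records["BETA_G"] + records["BETA_GXE"], records["P_JOINT"]
    out = pd.DataFrame(
        {"SNP": records["SNP"], "A1": records["A1"], "WEIGHT": weight, "P": p}
    ).dropna(subset=["WEIGHT", "P"])
    return out.reset_index(drop=True)


def _orient_weights(
    weights: pd.DataFrame, panel: GenotypePanel, drop_ambiguous: bool
) -> pd.DataFrame:
    """Match weight rows to panel SNPs, flipping sign where A1/A2 are swapped."""
    meta = panel.snp_meta.set_index("snp_id")
    rows = []
    for row in weights.itertuples(index=False):
        if row.SNP not in meta.index:
            continue
        a1, a2 = meta.loc[row.SNP, "a1"], meta.loc[row.SNP, "a2"]
        if drop_ambiguous and frozenset((a1, a2)) in _AMBIGUOUS:
            continue
        if row.A1 == a1:
            rows.append((row.SNP, row.WEIGHT, row.P, False))
        elif row.A1 == a2:
            rows.append((row.SNP, row.WEIGHT, row.P, True))
        # allele mismatch: unresolvable, drop
    return pd.DataFrame(rows, columns=["SNP", "WEIGHT", "P", "flip"])


def score(
    target: GenotypePanel,
    weights: pd.DataFrame,
    p_threshold: float = 1.0,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Weighted allele-dosage sum per sample (FID, IID, SCORE, SCORE_STD, N_SNPS).

    Dosage is counted on the weight table's effect allele (flipped where
    the panel codes the other allele as A1); missing dosages are imputed
    as twice the target effect-allele frequency.
    """
    matched = _orient_weights(weights, target, drop_ambiguous)
    matched = matched[matched["P"] <= p_threshold]
    if matched.empty:
        raise ValueError(
            f"no SNP passes p-threshold {p_threshold} after allele matching"
        )
    col_of = {s: i for i, s in enumerate(target.snp_meta["snp_id"])}
    cols = np.array([col_of[s] for s in matched["SNP"]])
    dos = target.dosages[:, cols].copy()
    freqs = target.allele_frequency()[cols]
    miss = ~np.isfinite(dos)
    if miss.any():
        dos[miss] = np.broadcast_to(2.0 * freqs, dos.shape)[miss]
    # orient every weight to the panel's A1 coding: swapping a weight row's
    # effect allele while negating its weight then leaves scores unchanged
    flip = matched["flip"].to_numpy()
    w = matched["WEIGHT"].to_numpy().copy()
    w[flip] = -w[flip]
    raw = dos @ w
    sd = raw.std()
    out = pd.DataFrame(target.sample_ids, columns=["FID", "IID"])
    out["SCORE"] = raw
    out["SCORE_STD"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    out["N_SNPS"] = len(matched)
    out["P_THRESHOLD"] = p_threshold
    return out


class PrsScorer(BaseEstimator, TransformerMixin):
    """Clump + threshold polygenic scorer (sklearn transformer shape).

    ``fit`` builds the weight table from scan summary statistics (and
    clumps against a reference panel when given); ``transform`` scores a
    target panel into per-sample profiles.
    """

    def __init__(
        self,
        scheme: str = "additive",
        p_threshold: float = 1.0,
        clump_r2: float = 0.1,
        clump_window_kb: float = 250.0,
        clump_p1: float = 1.0,
        drop_ambiguous: bool = False,
    ):
        self.scheme = scheme
        self.p_threshold = p_threshold
        self.clump_r2 = clump_r2
        self.clump_window_kb = clump_window_kb
        self.clump_p1 = clump_p1
        self.drop_ambiguous = drop_ambiguous

    def fit(self, sumstats: pd.DataFrame, reference: GenotypePanel | None = None):
        weights = build_weights(sumstats, self.scheme)
        if reference is not None:
            p_col = {"additive": "P", "gxe": "P_GXE", "joint": "P_JOINT"}[self.scheme]
            kept = clump(
                sumstats,
                reference,
                r2_threshold=self.clump_r2,
                window_kb=self.clump_window_kb,
                p1=self.clump_p1,
                p_col=p_col,
            )
            weights = weights[weights["SNP"].isin(kept)].reset_index(drop=True)
        self.weights_ = weights
        self.n_snps_ = len(weights)
        return self

    def transform(self, panel: GenotypePanel) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            raise ValueError("PrsScorer must be fitted before transform")
        return score(
            panel, self.weights_, self.p_threshold, drop_ambiguous=self.drop_ambiguous
        )


def threshold_search(
    target: GenotypePanel,
    weights: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    grid=DEFAULT_THRESHOLD_GRID,
) -> pd.DataFrame:
    """PRSice-style best-fit search: incremental R^2 of the score at each
    threshold in ``grid`` (thresholds with no passing SNP are skipped)."""
    from .evaluate import incremental_r2  # local import avoids a cycle

    y = np.asarray(phenotype, dtype=float)
    rows = []
    for thr in grid:
        try:
            prof = score(target, weights, p_threshold=thr)
        except ValueError:
            continue
        r2 = incremental_r2(y, prof["SCORE"].to_numpy(), covariates)
        rows.append({"p_threshold": thr, "n_snps": prof["N_SNPS"].iloc[0], "r2": r2})
    if not rows:
        raise ValueError("no threshold in the grid retains any SNP")
    out = pd.DataFrame(rows)
    out["best"] = out["r2"] == out["r2"].max()
    return out
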