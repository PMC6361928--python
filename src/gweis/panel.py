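"""In-memory genotype panel: sample x SNP dosage matrix plus per-SNP metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns required in :attr:`GenotypePanel.snp_meta`
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypePanel:
    """Biallelic dosages with SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array counting copies of the effect
        allele (A1), entries in ``{0, 1, 2}`` or ``nan`` for missing.
    snp_meta
        One row per SNP with columns ``snp_id, chrom, pos, a1, a2``.
        Positions are 1-based and strictly increasing within a chromosome.
    sample_ids
        ``(FID, IID)`` pairs, one per row of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sample x SNP matrix")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta missing columns: {missing}")
        if not self.sample_ids:
            self.sample_ids = [(f"F{i}", f"I{i}") for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")
        if (self.snp_meta["a1"].to_numpy() == self.snp_meta["a2"].to_numpy()).any():
            raise ValueError("effect allele must differ from other allele")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Effect-allele (A1) frequency per SNP, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            self.dosages[index],
            self.snp_meta.reset_index(drop=True),
            [self.sample_ids[i] for i in index],
        )

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            self.dosages[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )
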