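"""Whitespace/tab-delimited table readers with (FID, IID) sample joins."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .panel import GenotypePanel

log = logging.getLogger("gweis")

#: required columns per table kind (None -> at least one value column)
_SCHEMAS = {
    "phenotype": ["FID", "IID"],
    "covariate": ["FID", "IID"],
    "exposure": ["FID", "IID"],
    "sumstats": ["SNP", "CHR", "BP", "A1", "A2"],
    "weights": ["SNP", "A1", "WEIGHT", "P"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a typed analysis table; tab- and whitespace-delimited files parse identically."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; choose from {sorted(_SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: {kind} table missing columns {missing}")
    if kind in ("phenotype", "covariate", "exposure"):
        df["FID"] = df["FID"].astype(str)
        df["IID"] = df["IID"].astype(str)
        if df.duplicated(["FID", "IID"]).any():
            dupes = df[df.duplicated(["FID", "IID"])][["FID", "IID"]].head()
            raise ValueError(f"{path}: duplicated sample keys, e.g.\n{dupes}")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: {kind} table has no value column")
    return df


def align_samples(panel: GenotypePanel, table: pd.DataFrame) -> pd.DataFrame:
    """Reindex a (FID, IID)-keyed table to the panel's sample order.

    Samples absent from the panel are dropped (and counted in the log);
    panel samples absent from the table get NaN rows.
    """
    keyed = table.set_index(["FID", "IID"])
    panel_index = pd.MultiIndex.from_tuples(panel.sample_ids, names=["FID", "IID"])
    dropped = len(keyed.index.difference(panel_index))
    matched = len(keyed.index.intersection(panel_index))
    log.info("sample join: %d matched, %d dropped (not in panel)", matched, dropped)
    return keyed.reindex(panel_index)
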