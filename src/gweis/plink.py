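"""PLINK 1.9 binary genotype I/O (bed/bim/fam triplets).

The bed payload is SNP-major: after the three magic bytes
``0x6C 0x1B 0x01`` each SNP occupies ``ceil(n_samples / 4)`` bytes, four
samples per byte starting from the two low-order bits.  Two-bit codes:

====  =======================  ============
code  genotype                 A1 dosage
====  =======================  ============
00    homozygous A1            2
01    missing                  nan
10    heterozygous             1
11    homozygous A2            0
====  =======================  ============
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

MAGIC = bytes((0x6C, 0x1B, 0x01))

# code -> A1 dosage, and its inverse
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_MISSING_CODE = 0b01


def _byte_decode_table() -> np.ndarray:
    """(256, 4) table mapping a payload byte to four A1 dosages."""
    table = np.empty((256, 4))
    for byte in range(256):
        for slot in range(4):
            table[byte, slot] = _CODE_TO_DOSAGE[(byte >> (2 * slot)) & 0b11]
    return table


_DECODE = _byte_decode_table()


class PlinkFormatError(ValueError):
    """Malformed bed/bim/fam triplet."""


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam for a genotype panel."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_samples, panel.n_snps
    bytes_per_snp = math.ceil(n / 4)

    codes = np.full((m, bytes_per_snp * 4), _MISSING_CODE, dtype=np.uint8)
    dos = panel.dosages.T  # SNP-major
    for value, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dos == value] = code
    # samples beyond n pad the final byte with the missing code (PLINK convention)
    codes[:, n:] = _MISSING_CODE
    shifted = codes.reshape(m, bytes_per_snp, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    payload = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC)
        fh.write(payload.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": panel.snp_meta["chrom"],
            "snp_id": panel.snp_meta["snp_id"],
            "cm": 0,
            "pos": panel.snp_meta["pos"],
            "a1": panel.snp_meta["a1"],
            "a2": panel.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": [s[0] for s in panel.sample_ids],
            "iid": [s[1] for s in panel.sample_ids],
            "pid": 0,
            "mid": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a bed/bim/fam triplet into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    for suffix in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(suffix).exists():
            raise PlinkFormatError(f"missing {prefix.with_suffix(suffix)}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    bytes_per_snp = math.ceil(n / 4)

    raw = bed_path.read_bytes()
    if raw[:3] != MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (expected {MAGIC.hex()}, SNP-major)"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    expected = bytes_per_snp * m
    if payload.size != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload has {payload.size} bytes, expected {expected} "
            f"({m} SNPs x {bytes_per_snp} bytes for {n} samples)"
        )

    dosages = _DECODE[payload.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n].T
    meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    sample_ids = list(zip(fam["fid"], fam["iid"]))
    return GenotypePanel(np.ascontiguousarray(dosages), meta, sample_ids)
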