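"""Minimal PLINK 1 BED/BIM/FAM reader and writer.

Implements the SNP-major binary layout: a 3-byte magic header
(0x6c, 0x1b, 0x01) followed by ceil(n_samples / 4) bytes per variant, two
bits per genotype. Dosages count the A1 allele of the .bim file:

    0b00 -> 2 (A1/A1)   0b10 -> 1 (A1/A2)   0b11 -> 0 (A2/A2)   0b01 -> NaN

Only what this package needs: biallelic hard calls, no sample-major files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage (A1 count); 1 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

BIM_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bed(prefix: str | Path):
    """Read ``prefix``.bed/.bim/.fam into (dosages, bim, fam).

    Returns the n_samples x n_variants float dosage matrix (NaN missing),
    the .bim table and the .fam table as DataFrames.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=BIM_COLUMNS, dtype={"chrom": str, "id": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=FAM_COLUMNS, dtype={"fid": str, "iid": str})
    n, p = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    stride = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != stride * p:
        raise ValueError(f"{prefix}.bed: expected {stride * p} genotype bytes, got {body.size}")
    body = body.reshape(p, stride)
    # unpack the four 2-bit genotypes of each byte, little end first
    codes = np.empty((p, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return dosages, bim, fam


def write_bed(prefix: str | Path, dosages: np.ndarray, bim: pd.DataFrame,
              fam: pd.DataFrame) -> None:
    """Write dosages + metadata as ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if len(fam) != n or len(bim) != p:
        raise ValueError("metadata shape does not match dosage matrix")
    codes = np.full((p, n), 0b01, dtype=np.uint8)  # missing
    for value, code in _DOSAGE_TO_CODE.items():
        codes[dosages.T == value] = code
    valid = np.isnan(dosages.T) | np.isin(dosages.T, list(_DOSAGE_TO_CODE))
    if not valid.all():
        bad = dosages.T[~valid].flat[0]
        raise ValueError(f"non-integer SNP dosage {bad!r} cannot be bit-packed")
    stride = (n + 3) // 4
    padded = np.zeros((p, stride * 4), dtype=np.uint8)
    padded[:, :n] = codes
    body = np.zeros((p, stride), dtype=np.uint8)
    for k in range(4):
        body |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(body.tobytes())
    bim[BIM_COLUMNS].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam[FAM_COLUMNS].to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
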