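"""Minimal PLINK 1 binary fileset (.bed/.bim/.fam) reader and writer.

Implements the bed v1.00 SNP-major layout: a three-byte header
(0x6c, 0x1b, 0x01) followed by ceil(n/4) bytes per variant, two bits per
sample.  Two-bit codes follow the PLINK convention::

    00  homozygous A1      -> dosage 2 (count of A1 allele)
    01  missing            -> NaN
    10  heterozygous       -> dosage 1
    11  homozygous A2      -> dosage 0

Only the pieces the pipeline needs are implemented; no support for
individual-major files or the PLINK 2 formats.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

# dosage of A1 for the four 2-bit codes, NaN = missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_bim(prefix: str | Path) -> pd.DataFrame:
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None, names=BIM_COLUMNS,
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    return bim


def read_fam(prefix: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None, names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str},
    )


def read_bed(prefix: str | Path, snp_indices: np.ndarray | None = None) -> np.ndarray:
    """Read dosages (n_samples x n_snps, A1 counts, NaN for missing).

    Parameters
    ----------
    snp_indices
        Optional variant subset (indices into the .bim order); the returned
        columns follow this order.
    """
    bim = read_bim(prefix)
    fam = read_fam(prefix)
    n, p = len(fam), len(bim)
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed v1.00 file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise ValueError(
            f"{prefix}.bed has {body.size} data bytes; expected {bytes_per_snp * p}"
        )
    body = body.reshape(p, bytes_per_snp)
    if snp_indices is not None:
        body = body[np.asarray(snp_indices)]
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(body.shape[0], -1)[:, :n]
    return _CODE_TO_DOSAGE[codes].T.copy()


def write_bed(
    prefix: str | Path,
    dosages: np.ndarray,
    bim: pd.DataFrame,
    fam: pd.DataFrame | None = None,
) -> None:
    """Write an A1-dosage matrix (n x p, NaN = missing) as a bed/bim/fam triple."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    if len(bim) != p:
        raise ValueError(f"bim has {len(bim)} rows for {p} dosage columns")
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": [f"F{i}" for i in range(n)],
                "iid": [f"I{i}" for i in range(n)],
                "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
            }
        )
    codes = np.full(dosages.T.shape, 0b01, dtype=np.uint8)  # default missing
    codes[dosages.T == 2] = 0b00
    codes[dosages.T == 1] = 0b10
    codes[dosages.T == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.full((p, pad), 0b01, dtype=np.uint8)], axis=1
        )
    packed = (
        codes.reshape(p, -1, 4) << (np.arange(4, dtype=np.uint8) * 2)[None, None, :]
    ).sum(axis=2, dtype=np.uint8)
    Path(f"{prefix}.bed").write_bytes(_MAGIC + packed.tobytes())
    bim[BIM_COLUMNS].to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam[FAM_COLUMNS].to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
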