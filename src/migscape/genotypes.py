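"""Genotype container and PLINK binary-trio (.bed/.bim/.fam) input/output.

Genotypes are stored as an ``(n_samples, n_snps)`` int8 array of alternate
allele counts {0, 1, 2}, with -1 marking a missing call.  SNP metadata
(chromosome, position, alleles) and per-sample records (id, longitude,
latitude, population, optional language) travel with the matrix in pandas
DataFrames so that filters can report exactly what they removed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: 2-bit PLINK .bed codes -> allele count of allele-2 ("alt"), SNP-major.
#: 0b00 = hom a1 (2 copies of a1 -> 0 alt), 0b01 = missing, 0b10 = het,
#: 0b11 = hom a2.  We count the a2 allele, matching the .bim column order
#: (a1 = usually minor, a2 = usually major) read back untouched.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_SNP_COLS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
_SAMPLE_COLS = ["sample_id", "lon", "lat", "pop"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with metadata.

    Attributes
    ----------
    calls:
        ``(n, p)`` int8 array; entries in {0, 1, 2} or -1 for missing.
    snps:
        DataFrame with columns ``chrom, snp_id, cm, pos, a1, a2`` (one row
        per SNP, aligned with the columns of ``calls``).
    samples:
        DataFrame with at least ``sample_id``; typically also ``lon, lat,
        pop`` and optionally ``language``.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x snps)")
        if len(self.snps) != self.calls.shape[1]:
            raise ValueError("snps metadata does not match call matrix width")
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError("sample table does not match call matrix height")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs by positional index (order preserved)."""
        return GenotypeMatrix(
            self.calls[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset samples by positional index (order preserved)."""
        return GenotypeMatrix(
            self.calls[index, :],
            self.snps.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def missing_rate_per_snp(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major .bed, v1 magic)."""
    prefix = Path(prefix)
    n, p = g.calls.shape
    # .fam: fid iid pat mat sex pheno
    fam = pd.DataFrame(
        {
            "fid": g.samples["sample_id"],
            "iid": g.samples["sample_id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = g.snps[["chrom", "snp_id", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    out = np.empty((p, n_bytes), dtype=np.uint8)
    codes = np.empty((p, 4 * n_bytes), dtype=np.uint8)
    calls = g.calls.T  # SNP-major
    padded = np.full((p, 4 * n_bytes), 0, dtype=np.int8)
    padded[:, :n] = calls
    for count, code in _COUNT_TO_CODE.items():
        codes[padded == count] = code
    codes[:, n:] = 0b00  # pad bits
    out = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a ``prefix``.bed/.bim/.fam trio into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=_SNP_COLS,
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major v1 .bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    body = body.reshape(p, n_bytes)
    codes = np.empty((p, 4 * n_bytes), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    calls = _CODE_TO_COUNT[codes[:, :n]].T
    samples = pd.DataFrame({"sample_id": fam["iid"].astype(str)})
    return GenotypeMatrix(calls, bim, samples)


def write_coordinates(samples: pd.DataFrame, path: str | Path) -> None:
    """Write the sample coordinate table (TSV: sample_id lon lat pop language)."""
    cols = [c for c in ["sample_id", "lon", "lat", "pop", "language"] if c in samples]
    samples[cols].to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})
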