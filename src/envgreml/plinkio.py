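"""PLINK 1 binary genotype I/O and the in-memory genotype container.

Dosages count copies of the A1 allele in the ``.bim`` file, the usual
additive coding.  The ``.bed`` file is the v1.00 SNP-major layout
(magic bytes ``0x6c 0x1b 0x01``); each variant is packed 4 samples per
byte with the 2-bit codes

    ``00`` homozygous A1 (dosage 2), ``01`` missing,
    ``10`` heterozygous (dosage 1), ``11`` homozygous A2 (dosage 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError, FormatError

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# byte -> 4 dosages, LSB pair first; nan marks missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DECODE_LUT = np.empty((256, 4))
for _b in range(256):
    for _k in range(4):
        _DECODE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]

_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


@dataclass
class GenotypeMatrix:
    """n x M biallelic SNP dosages with sample/variant metadata.

    ``variants`` carries columns ``chrom, snp, cm, pos, a1, a2`` in bim
    order; ``dosages[i, m]`` is the A1-allele count of sample i at
    variant m, ``nan`` when missing.
    """

    samples: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise DimensionError(
                f"dosages {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples / {len(self.variants)} variants"
            )
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample IDs")
        snp_ids = self.variants["snp"]
        if snp_ids.duplicated().any():
            raise FormatError("duplicate variant IDs")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Per-variant A1 allele frequency, missing dosages excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def standardized(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Column-standardized dosages (x - 2p) / sqrt(2p(1-p)); missing -> 0.

        Monomorphic columns are returned as all-zero rather than dividing
        by zero.
        """
        p = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        denom = np.sqrt(2.0 * p * (1.0 - p))
        poly = denom > 0
        z = np.zeros_like(self.dosages)
        z[:, poly] = (self.dosages[:, poly] - 2.0 * p[poly]) / denom[poly]
        np.nan_to_num(z, copy=False)
        return z

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in s],
            variants=self.variants.iloc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(s, v)],
        )


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a ``.bed/.bim/.fam`` triplet into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    samples = fam["iid"].tolist()
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate individual IDs in .fam")

    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise FormatError(
            f"bad .bed magic bytes {raw[:3].hex()} (expected {_MAGIC.hex()}: "
            "PLINK1 SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f".bed has {len(raw)} bytes, expected {expected} for n={n}, M={m}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    dosages = _DECODE_LUT[body].reshape(m, bytes_per_snp * 4)[:, :n].T.copy()
    return GenotypeMatrix(samples=samples, variants=bim, dosages=dosages)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``G`` as a PLINK1 bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.dosages.shape

    fam = pd.DataFrame(
        {
            "fid": G.samples,
            "iid": G.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    G.variants[["chrom", "snp", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )

    codes = np.full((n, m), 0b01, dtype=np.uint8)  # missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[G.dosages == dosage] = code
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.full((pad, m), 0b11, dtype=np.uint8)])
    quads = codes.T.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
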