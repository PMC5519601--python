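"""Genomic relationship matrix (GRM) construction, GCTA-format I/O and
relatedness pruning.

The estimator is the allele-frequency standardized form of Yang et al. /
VanRaden method I:

    A_jk = (1/M_jk) * sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m))

with p_m estimated from the sample, monomorphic markers skipped, missing
dosages mean-imputed (contributing zero to the numerator) and M_jk the
number of markers non-missing in both members of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DimensionError, FormatError, ModelError
from .plinkio import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric genomic similarity matrix with aligned sample IDs."""

    samples: list
    values: np.ndarray
    n_snps_used: np.ndarray  # per-pair count of markers entering the average

    def __post_init__(self):
        self.samples = list(self.samples)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise DimensionError("GRM values not square / misaligned with samples")
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample IDs in GRM")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ModelError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.samples)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in GRM") from None

    def subset(self, ids) -> "GRM":
        idx = self.index_of(ids)
        return GRM(
            samples=[self.samples[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            n_snps_used=self.n_snps_used[np.ix_(idx, idx)],
        )


def compute_grm(G: GenotypeMatrix) -> GRM:
    """Build the standardized GRM from dosages.

    On complete data this equals ``Z Z' / M`` with Z the column-standardized
    dosage matrix.  With missingness, each pair is averaged over the markers
    observed in both individuals.
    """
    p = G.freqs
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ModelError("no polymorphic SNPs available for GRM construction")
    Gp = G.subset(variant_idx=np.nonzero(poly)[0])
    z = Gp.standardized()  # missing -> 0 contribution
    observed = (~Gp.missing_mask).astype(float)
    n_pair = observed @ observed.T
    if (n_pair == 0).any():
        raise ModelError("some sample pair shares no observed SNPs")
    values = (z @ z.T) / n_pair
    values = 0.5 * (values + values.T)
    return GRM(samples=Gp.samples, values=values, n_snps_used=n_pair)


def write_gcta_grm(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA binary dialect: float32 lower triangle (row-major,
    diagonal included) in ``.grm.bin``, float32 pair counts in
    ``.grm.N.bin`` and a two-column ``.grm.id``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tril = np.tril_indices(grm.n)
    grm.values[tril].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps_used[tril].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.samples:
            fh.write(f"{s}\t{s}\n")


def read_gcta_grm(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if vals.size != n_tri:
        raise FormatError(f".grm.bin holds {vals.size} values, expected {n_tri}")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if counts.size not in (1, n_tri):
        raise FormatError(".grm.N.bin size inconsistent with id file")
    if counts.size == 1:
        counts = np.full(n_tri, counts[0])

    tril = np.tril_indices(n)
    values = np.zeros((n, n))
    values[tril] = vals
    values = values + np.tril(values, -1).T
    npairs = np.zeros((n, n))
    npairs[tril] = counts
    npairs = npairs + np.tril(npairs, -1).T
    return GRM(samples=ids, values=values.astype(float), n_snps_used=npairs)


def prune_related(grm: GRM, threshold: float = 0.05) -> list:
    """Greedy relatedness pruning: repeatedly drop the individual involved
    in the most pairs with relationship > ``threshold`` until none remain.

    Ties are broken by sample order (the later sample is dropped), making
    the result deterministic.  Returns the retained sample IDs in their
    original order.
    """
    if threshold <= 0:
        raise ModelError(f"relatedness threshold must be positive, got {threshold}")
    n = grm.n
    conflict = grm.values > threshold
    np.fill_diagonal(conflict, False)
    active = np.ones(n, dtype=bool)
    degree = conflict.sum(axis=1).astype(int)
    while True:
        if degree[active].max(initial=0) == 0:
            break
        cand = np.nonzero(active & (degree == degree[active].max()))[0]
        drop = cand[-1]  # later sample loses on ties
        active[drop] = False
        partners = np.nonzero(conflict[drop] & active)[0]
        degree[partners] -= 1
        degree[drop] = 0
    return [grm.samples[i] for i in np.nonzero(active)[0]]
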