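"""Genotype quality control: Hardy-Weinberg test and marker/sample filters.

Default thresholds follow standard GWAS practice for imputed biobank
genotypes: MAF > 0.01, HWE p >= 1e-4, per-variant missingness <= 0.05,
per-sample missingness <= 0.05.  Variant filters are applied first, then
sample missingness is evaluated on the surviving variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DomainError
from .plinkio import GenotypeMatrix


def hwe_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Chi-square (1 df, no continuity correction) test of Hardy-Weinberg
    proportions from genotype counts.

    Returns the p-value for departure from HW expectation.
    """
    counts = np.array([n_hom_a1, n_het, n_hom_a2], dtype=float)
    if (counts < 0).any():
        raise DomainError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise DomainError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: HW trivially satisfied
    chi2 = np.sum((counts - expected) ** 2 / expected)
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """Bookkeeping of removals per filter; removals sum to input - output."""

    n_variants_in: int
    n_samples_in: int
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_var_missing: int = 0
    removed_sample_missing: int = 0
    thresholds: dict = field(default_factory=dict)
    empty_output: bool = False

    @property
    def n_variants_out(self) -> int:
        return (
            self.n_variants_in
            - self.removed_maf
            - self.removed_hwe
            - self.removed_var_missing
        )

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.removed_sample_missing

    def to_frame(self):
        import pandas as pd

        rows = [
            ("variants_in", self.n_variants_in),
            ("removed_maf", self.removed_maf),
            ("removed_hwe", self.removed_hwe),
            ("removed_variant_missingness", self.removed_var_missing),
            ("variants_out", self.n_variants_out),
            ("samples_in", self.n_samples_in),
            ("removed_sample_missingness", self.removed_sample_missing),
            ("samples_out", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["filter", "count"])


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    var_miss_max: float = 0.05,
    sample_miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker-level then sample-level QC.

    Variants are removed when MAF <= ``maf_min``, HWE p < ``hwe_p_min``
    or missingness > ``var_miss_max`` (evaluated in that order for
    reporting; a variant is counted against the first filter it fails).
    Samples with missingness > ``sample_miss_max`` over the surviving
    variants are then removed.
    """
    if not 0 <= maf_min < 0.5:
        raise DomainError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not 0 <= hwe_p_min <= 1:
        raise DomainError("hwe_p_min must be a probability")
    if not (0 <= var_miss_max <= 1 and 0 <= sample_miss_max <= 1):
        raise DomainError("missingness thresholds must be proportions")

    report = QCReport(
        n_variants_in=G.n_variants,
        n_samples_in=G.n_samples,
        thresholds={
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "var_miss_max": var_miss_max,
            "sample_miss_max": sample_miss_max,
        },
    )

    miss = G.missing_mask
    var_miss_rate = miss.mean(axis=0)
    freqs = G.freqs
    maf = np.minimum(freqs, 1 - freqs)
    # nan freq means all-missing variant; fails the missingness filter
    maf = np.where(np.isnan(maf), 0.5, maf)

    keep = np.ones(G.n_variants, dtype=bool)
    fail_maf = maf <= maf_min
    report.removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    hwe_p = np.ones(G.n_variants)
    for m in np.nonzero(keep)[0]:
        d = G.dosages[:, m]
        d = d[~np.isnan(d)]
        if d.size:
            hwe_p[m] = hwe_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    fail_hwe = keep & (hwe_p < hwe_p_min)
    report.removed_hwe = int(fail_hwe.sum())
    keep &= ~fail_hwe

    fail_miss = keep & (var_miss_rate > var_miss_max)
    report.removed_var_missing = int(fail_miss.sum())
    keep &= ~fail_miss

    variant_idx = np.nonzero(keep)[0]
    if variant_idx.size == 0:
        report.empty_output = True
        out = G.subset(variant_idx=variant_idx)
        return out, report

    sample_miss_rate = miss[:, variant_idx].mean(axis=1)
    keep_samples = sample_miss_rate <= sample_miss_max
    report.removed_sample_missing = int((~keep_samples).sum())

    out = G.subset(sample_idx=np.nonzero(keep_samples)[0], variant_idx=variant_idx)
    if out.n_samples == 0:
        report.empty_output = True
    return out, report
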