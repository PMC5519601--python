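"""Synthetic genotype and environment-stratified cohort simulation.

The generator mirrors the GREML model itself: an infinitesimal
architecture in which every SNP is causal with Gaussian effects.
Cross-environment genetic covariance is induced at the SNP-effect level --
K correlated per-SNP effect vectors (a matrix square root of the K x K
genetic covariance applied to independent standard-normal draws) -- so
that disjoint groups of individuals share genetic architecture without
sharing environments, exactly the design the multivariate GREML estimates.
Genotypes are drawn in linkage equilibrium: LD is irrelevant to the
variance-component identities under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DimensionError, DomainError, ModelError, SelectionError
from .phenotype import FOUR_GROUPS
from .plinkio import GenotypeMatrix
from .selection import SelectionRegime


class EffectMatrix:
    """M x K per-SNP effect vectors attached to a simulated cohort.

    Wrapped so that pandas ``attrs`` equality checks (which use ``==``)
    stay well-defined for array payloads.
    """

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def __array__(self, dtype=None, copy=None):
        return self.values if dtype is None else self.values.astype(dtype)

    def __getitem__(self, key):
        return self.values[key]

    def __eq__(self, other):
        return isinstance(other, EffectMatrix) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


@dataclass(frozen=True)
class CovariateSpec:
    """A simulated confounder: kind in {continuous, binary, factor} with a
    linear effect on the phenotype (for factors the effect multiplies the
    level index, first level as reference)."""

    name: str
    kind: str
    effect: float

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "factor"):
            raise DomainError(f"unknown covariate kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """True parameters of a G-by-E cohort.

    ``sigma_g`` is the K x K genetic covariance across environment groups
    (per-group genetic variances on the diagonal); ``sigma_e`` the
    per-group residual variances.  Each sample belongs to exactly one
    group (no repeated measures, hence no residual covariance).
    """

    n_per_group: list
    n_snps: int
    sigma_g: np.ndarray
    sigma_e: np.ndarray
    maf_range: tuple = (0.05, 0.5)
    covariate_spec: list = field(default_factory=list)
    group_labels: list | None = None
    phenotype_transform: str | None = None  # None | 'exponential' | 'ordinal'
    selection: tuple | None = None  # optional (SelectionRegime,) applied downstream
    seed: int | None = None

    def __post_init__(self):
        self.n_per_group = [int(n) for n in self.n_per_group]
        self.sigma_g = np.atleast_2d(np.asarray(self.sigma_g, dtype=float))
        self.sigma_e = np.atleast_1d(np.asarray(self.sigma_e, dtype=float))
        K = len(self.n_per_group)
        if K < 1 or any(n < 1 for n in self.n_per_group):
            raise DimensionError("every group needs at least one sample")
        if self.sigma_g.shape != (K, K):
            raise DimensionError(
                f"sigma_g shape {self.sigma_g.shape} != ({K}, {K})"
            )
        if not np.allclose(self.sigma_g, self.sigma_g.T, atol=1e-10):
            raise ModelError("sigma_g must be symmetric")
        if np.linalg.eigvalsh(self.sigma_g).min() < -1e-8:
            raise ModelError("sigma_g must be positive semidefinite")
        if self.sigma_e.shape != (K,) or (self.sigma_e <= 0).any():
            raise ModelError("sigma_e must hold K positive residual variances")
        if self.group_labels is None:
            self.group_labels = (
                list(FOUR_GROUPS) if K == 4 else [f"E{k + 1}" for k in range(K)]
            )
        if len(self.group_labels) != K:
            raise DimensionError("group_labels length must equal K")
        if self.phenotype_transform not in (None, "exponential", "ordinal"):
            raise DomainError(
                f"unknown phenotype_transform {self.phenotype_transform!r}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.n_per_group)

    @property
    def h2(self) -> np.ndarray:
        vg = np.diag(self.sigma_g)
        return vg / (vg + self.sigma_e)


def gxe_config(
    n_per_group,
    h2,
    r_g,
    n_snps: int,
    maf_range=(0.05, 0.5),
    covariate_spec=(),
    seed: int | None = None,
    **kwargs,
) -> SimulationConfig:
    """Convenience constructor: per-group heritabilities plus a genetic
    correlation (scalar or K x K matrix), phenotypic variance 1 per group."""
    K = len(n_per_group)
    h2 = np.full(K, h2, dtype=float) if np.isscalar(h2) else np.asarray(h2, float)
    if np.isscalar(r_g):
        R = np.full((K, K), float(r_g))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(r_g, dtype=float)
    sd_g = np.sqrt(h2)
    sigma_g = R * np.outer(sd_g, sd_g)
    sigma_e = 1.0 - h2
    return SimulationConfig(
        n_per_group=list(n_per_group),
        n_snps=n_snps,
        sigma_g=sigma_g,
        sigma_e=sigma_e,
        maf_range=maf_range,
        covariate_spec=list(covariate_spec),
        seed=seed,
        **kwargs,
    )


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range=(0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw unlinked biallelic dosages: per SNP, p ~ U(maf_range) and
    dosage ~ Binomial(2, p).  Deterministic given the seed."""
    if n_samples < 1 or n_snps < 1:
        raise DimensionError(
            f"need positive dimensions, got n={n_samples}, M={n_snps}"
        )
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise DomainError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if not 0 <= missing_rate < 1:
        raise DomainError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed) if rng is None else rng
    p = rng.uniform(lo, hi, n_snps)
    dosages = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        dosages[rng.random((n_samples, n_snps)) < missing_rate] = np.nan

    per_chrom = -(-n_snps // 22)
    chrom = 1 + np.arange(n_snps) // per_chrom
    pos = 1000 * (1 + np.arange(n_snps) % per_chrom)
    variants = pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "snp": [f"snp{m + 1}" for m in range(n_snps)],
            "cm": 0.0,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    variants.attrs["true_freqs"] = p
    samples = [f"id{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD matrix (eigen form, robust to singular S)."""
    w, v = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


_FOUR_GROUP_LABELS = {
    "B&NS": ("yes", "no"),
    "B&S": ("yes", "yes"),
    "NB&NS": ("no", "no"),
    "NB&S": ("no", "yes"),
}


def simulate_gxe_cohort(
    G: GenotypeMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Generate an environment-stratified cohort on top of genotypes ``G``.

    Per-SNP effect vectors for the K groups are drawn jointly so that the
    across-group covariance of the genetic values equals ``sigma_g``; the
    phenotype is covariate effects + genetic value + residual.  Returns a
    cohort table with one row per sample (columns: sample_id, group,
    breastfed, maternal_smoking, sex, phenotype, true_g, covariates).
    """
    K = config.n_groups
    n_total = sum(config.n_per_group)
    if n_total > G.n_samples:
        raise DimensionError(
            f"groups need {n_total} samples but genotype pool has {G.n_samples}"
        )
    rng = np.random.default_rng(config.seed)

    sub = G.subset(sample_idx=np.arange(n_total))
    W = sub.standardized()
    M = sub.n_variants

    L = _psd_factor(config.sigma_g / M)
    B = rng.standard_normal((M, K)) @ L.T  # per-SNP effects, cov = sigma_g/M
    g_all = W @ B  # n_total x K

    group_idx = np.repeat(np.arange(K), config.n_per_group)
    g = g_all[np.arange(n_total), group_idx]
    e = rng.normal(0.0, np.sqrt(config.sigma_e[group_idx]))

    data = {
        "sample_id": sub.samples,
        "group": [config.group_labels[k] for k in group_idx],
        "sex": np.where(rng.random(n_total) < 0.5, "M", "F"),
    }
    fixed = np.zeros(n_total)
    for spec in config.covariate_spec:
        if spec.kind == "continuous":
            x = rng.standard_normal(n_total)
            fixed += spec.effect * x
            data[spec.name] = x
        elif spec.kind == "binary":
            x = (rng.random(n_total) < 0.5).astype(float)
            fixed += spec.effect * x
            data[spec.name] = x
        else:  # factor with 4 levels, first as reference
            lev = rng.integers(0, 4, n_total)
            fixed += spec.effect * lev
            data[spec.name] = np.array([f"L{v}" for v in lev])

    y = fixed + g + e
    if config.phenotype_transform == "exponential":
        y = np.exp(y / 2.0)
    elif config.phenotype_transform == "ordinal":
        edges = np.quantile(y, [0.25, 0.5, 0.75])
        y = np.digitize(y, edges).astype(float)

    cohort = pd.DataFrame(data)
    if set(config.group_labels) <= set(_FOUR_GROUP_LABELS):
        bf, sm = zip(*(_FOUR_GROUP_LABELS[gl] for gl in cohort["group"]))
        cohort["breastfed"], cohort["maternal_smoking"] = bf, sm
    else:
        cohort["breastfed"] = "unknown"
        cohort["maternal_smoking"] = "unknown"
    cohort["phenotype"] = y
    cohort["true_g"] = g
    cohort.attrs["effect_matrix"] = EffectMatrix(B)
    return cohort


def apply_selection(
    cohort: pd.DataFrame,
    regime: SelectionRegime,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Truncation-select cohort rows: keep samples whose selection variable
    falls in (t1, t2).

    The selection variable is the standardized phenotype when ``regime.r``
    is 1, otherwise a variable with correlation r to it.  The realized
    selected proportion is recorded in ``result.attrs``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    y = cohort[phenotype_col].to_numpy(dtype=float)
    sd = y.std()
    if sd == 0:
        raise SelectionError("constant phenotype; selection undefined", 0.0)
    z = (y - y.mean()) / sd
    r = regime.r
    if r == 1.0:
        s = z
    else:
        s = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(len(z))
    keep = (s > regime.t1) & (s < regime.t2)
    prop = float(keep.mean())
    if not keep.any():
        raise SelectionError("selection region retained no samples", prop)
    out = cohort.loc[keep].copy()
    out.attrs["realized_selection_proportion"] = prop
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table as TSV (header: sample_id, group, sex,
    phenotype, covariate columns)."""
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})
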