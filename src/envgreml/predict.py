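"""Cross-environment genomic prediction (GBLUP) and per-group GWAS.

GBLUP predicts target genetic values from discovery phenotypes under the
single-GRM mixed model y = 1 mu + g + e with var(g) = A sigma_g^2.  With
lambda = (1 - h2) / h2 the prediction is

    g_hat(target) = A[target, disc] (A[disc, disc] + lambda I)^{-1} (y - mu_hat)

which is identical to ridge regression on the standardized SNP matrix
(RR-BLUP) with ridge penalty M (1 - h2) / h2 when A = Z Z' / M.  Accuracy
is the Pearson correlation between predictions and observed (adjusted)
phenotypes in the target set, which must be disjoint from discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DimensionError, DomainError, ModelError
from .grm import GRM
from .plinkio import GenotypeMatrix


def gblup_predict(
    grm: GRM,
    discovery_ids,
    y_discovery,
    target_ids,
    h2: float,
) -> np.ndarray:
    """BLUP of target genetic values given discovery phenotypes.

    ``h2`` is the heritability used for shrinkage (estimate it in the
    discovery set or supply a fixed value).  Discovery and target must be
    disjoint.  Deterministic.
    """
    if not 0 < h2 < 1:
        raise DomainError(f"h2 must be in (0, 1), got {h2}")
    discovery_ids, target_ids = list(discovery_ids), list(target_ids)
    if set(discovery_ids) & set(target_ids):
        raise ModelError("discovery and target samples must be disjoint")
    y = np.asarray(y_discovery, dtype=float).ravel()
    if len(y) != len(discovery_ids):
        raise DimensionError("y_discovery length != number of discovery ids")
    di = grm.index_of(discovery_ids)
    ti = grm.index_of(target_ids)
    lam = (1.0 - h2) / h2
    add = grm.values[np.ix_(di, di)] + lam * np.eye(len(di))
    # absorb the intercept by GLS under C = A + lambda I (proportional to V/sg2)
    try:
        cinv_y = np.linalg.solve(add, y)
        cinv_1 = np.linalg.solve(add, np.ones_like(y))
    except np.linalg.LinAlgError as e:
        raise ModelError(f"singular mixed-model system: {e}") from None
    mu = float(cinv_y.sum() / cinv_1.sum())
    alpha = cinv_y - mu * cinv_1  # = (A + lam I)^{-1} (y - mu)
    return grm.values[np.ix_(ti, di)] @ alpha


def rrblup_predict(
    z_discovery: np.ndarray,
    z_target: np.ndarray,
    y_discovery,
    h2: float,
) -> np.ndarray:
    """Ridge-regression BLUP on standardized SNPs: identical to
    :func:`gblup_predict` when the GRM is Z Z' / M with the same Z."""
    if not 0 < h2 < 1:
        raise DomainError(f"h2 must be in (0, 1), got {h2}")
    y = np.asarray(y_discovery, dtype=float).ravel()
    n, m = z_discovery.shape
    lam = m * (1.0 - h2) / h2
    kern = z_discovery @ z_discovery.T + lam * np.eye(n)
    cinv_y = np.linalg.solve(kern, y)
    cinv_1 = np.linalg.solve(kern, np.ones(n))
    mu = float(cinv_y.sum() / cinv_1.sum())
    alpha = cinv_y - mu * cinv_1
    beta = z_discovery.T @ alpha  # SNP effects
    return z_target @ beta


def prediction_accuracy(predicted, observed) -> float:
    """Pearson correlation between predicted and observed phenotypes."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if len(p) != len(o) or len(p) < 3:
        raise DimensionError("need equal-length vectors with >= 3 entries")
    if p.std() == 0 or o.std() == 0:
        raise DomainError("constant vector: correlation undefined")
    return float(np.corrcoef(p, o)[0, 1])


@dataclass
class GwasResult:
    """Per-SNP association scan results."""

    table: pd.DataFrame  # snp, chrom, pos, beta, se, t, p, n, tested
    gw_threshold: float = 5e-8

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["tested"] & (t["p"] < self.gw_threshold)]

    def lambda_gc(self) -> float:
        return genomic_lambda(self.table.loc[self.table["tested"], "p"].to_numpy())


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor: median association chi-square
    (1 df) over its null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise DomainError("no p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def gwas_scan(
    G: GenotypeMatrix,
    y,
    sample_ids=None,
    gw_threshold: float = 5e-8,
) -> GwasResult:
    """Single-SNP least-squares association of (adjusted) phenotype on
    dosage, per SNP: slope, SE, t and p from simple linear regression on
    the samples non-missing at that SNP.  Monomorphic SNPs are flagged and
    not tested.  Covariate adjustment is expected upstream.
    """
    if sample_ids is not None:
        lookup = {s: i for i, s in enumerate(G.samples)}
        rows = np.array([lookup[s] for s in sample_ids], dtype=int)
        X = G.dosages[rows]
    else:
        X = G.dosages
    yv = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if len(yv) != n:
        raise DimensionError("phenotype length != sample count")
    if n <= 2:
        raise DimensionError("need more than 2 samples")
    if yv.std() == 0:
        raise DomainError("constant phenotype: association undefined")

    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    n_used = obs.sum(axis=0).astype(float)
    sx = (Xz * obs).sum(axis=0)
    sy = obs.T @ yv
    sxx = (Xz**2).sum(axis=0)
    sxy = Xz.T @ yv
    syy = obs.T @ (yv**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = sx / n_used
        mean_y = sy / n_used
        ssx = sxx - n_used * mean_x**2
        ssy = syy - n_used * mean_y**2
        sxy_c = sxy - n_used * mean_x * mean_y
        beta = sxy_c / ssx
        rss = ssy - beta * sxy_c
        df = n_used - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / ssx)
        t = beta / se

    tested = (ssx > 1e-12) & (df > 0)
    p = np.full(m, np.nan)
    p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), df[tested])
    p[tested] = np.clip(p[tested], np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "snp": G.variants["snp"].to_numpy(),
            "chrom": G.variants["chrom"].to_numpy(),
            "pos": G.variants["pos"].to_numpy(),
            "beta": np.where(tested, beta, np.nan),
            "se": np.where(tested, se, np.nan),
            "t": np.where(tested, t, np.nan),
            "p": p,
            "n": n_used.astype(int),
            "tested": tested,
        }
    )
    return GwasResult(table=table, gw_threshold=gw_threshold)
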