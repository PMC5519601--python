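"""Genome-wide G-by-E study design: joint K-variate GREML over environment
groups, all pairwise genetic-correlation contrasts with Wald tests against
r_G = 1, Bonferroni control over traits x contrasts, permutation nulls and
sex-stratified (eight-group) scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import BoundaryError, ConvergenceError, DomainError, EnvGremlError
from .grm import GRM
from .reml import (
    GeneticCorrelationResult,
    ModelBlocks,
    VarianceComponents,
    genetic_correlation,
    reml_fit,
)
from . import phenotype as _pheno


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error control: alpha / n_tests."""
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise DomainError(f"need at least one test, got {n_tests}")
    return alpha / n_tests


@dataclass
class GxEScanResult:
    """All pairwise cross-environment contrasts from one joint fit."""

    vc: VarianceComponents
    pairs: list  # GeneticCorrelationResult per pair
    h2: dict  # group label -> (estimate, se, p_vs_0)
    alpha: float
    n_traits: int
    threshold: float
    dropped_groups: list = field(default_factory=list)
    sex_contrast_pairs: list = field(default_factory=list)

    @property
    def n_contrasts(self) -> int:
        return len(self.pairs)

    @property
    def n_tests(self) -> int:
        return self.n_traits * self.n_contrasts

    def significant(self) -> list:
        return [p for p in self.pairs if p.p_vs_1 < self.threshold]

    def to_frame(self) -> pd.DataFrame:
        """Results table mirroring the usual layout: per-group h2 rows then
        pairwise r_G rows (test-type a: vs 0, b: vs 1)."""
        rows = []
        for label, (est, se, p) in self.h2.items():
            rows.append(("h2 " + label, est, se, p, "a"))
        for res in self.pairs:
            rows.append(
                (f"r_G ({res.labels[0]}, {res.labels[1]})",
                 res.r_g, res.se, res.p_vs_1, "b")
            )
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "p", "test"])


def _fit_groups(
    cohort: pd.DataFrame,
    grm: GRM,
    group_labels,
    pheno_col: str,
    min_group: int,
    **fit_kwargs,
):
    sizes = cohort["group"].value_counts()
    kept, dropped = [], []
    for g in group_labels:
        n = int(sizes.get(g, 0))
        if n < min_group:
            dropped.append(g)
        else:
            kept.append(g)
    if dropped:
        warnings.warn(
            f"dropping groups below the size floor ({min_group}): {dropped}"
        )
    if len(kept) < 2:
        raise DomainError("fewer than two groups above the size floor")
    blocks = ModelBlocks.from_cohort(
        cohort[cohort["group"].isin(kept)], grm, pheno_col=pheno_col, groups=kept
    )
    vc = reml_fit(blocks, grm, mode="gxe", **fit_kwargs)
    return vc, kept, dropped


def gxe_scan(
    cohort: pd.DataFrame,
    grm: GRM,
    mode: str = "four_group",
    pheno_col: str = "phenotype",
    alpha: float = 0.05,
    n_traits: int = 1,
    min_group: int = 50,
    group_col: str | None = None,
    **fit_kwargs,
) -> GxEScanResult:
    """One joint K-variate GREML fit across environment groups and all
    K(K-1)/2 pairwise genetic-correlation contrasts.

    ``mode`` is a stratification mode (see :func:`envgreml.phenotype.stratify`)
    applied to the environment label columns; pass ``group_col`` instead to
    use a precomputed group column.  The Bonferroni threshold reported is
    alpha / (n_traits * number of contrasts).
    """
    cohort = cohort.copy()
    if group_col is not None:
        cohort["group"] = cohort[group_col]
    else:
        cohort["group"] = _pheno.stratify(cohort, mode=mode, min_group=min_group)
    cohort = cohort[cohort["group"] != "excluded"]
    labels = sorted(cohort["group"].unique())

    vc, kept, dropped = _fit_groups(
        cohort, grm, labels, pheno_col, min_group, **fit_kwargs
    )
    K = len(kept)
    pairs = []
    for i, j in combinations(range(K), 2):
        try:
            pairs.append(genetic_correlation(vc, i, j))
        except EnvGremlError as e:
            # keep the contrast in the table (estimates undefined, e.g. a
            # genetic variance at its floor) so the K(K-1)/2 layout and the
            # multiple-testing accounting stay structural
            warnings.warn(f"contrast ({kept[i]}, {kept[j]}) undefined: {e}")
            pairs.append(
                GeneticCorrelationResult(
                    pair=(i, j), labels=(kept[i], kept[j]),
                    r_g=np.nan, se=np.nan, p_vs_0=np.nan, p_vs_1=np.nan,
                    h2_i=np.nan, h2_i_se=np.nan, h2_j=np.nan, h2_j_se=np.nan,
                )
            )
    h2 = {lab: vc.h2(i) for i, lab in enumerate(kept)}
    n_contrasts = K * (K - 1) // 2
    threshold = bonferroni_threshold(alpha, n_traits * n_contrasts)
    sex_pairs = [
        res for res in pairs
        if "_" in res.labels[0]
        and res.labels[0].rsplit("_", 1)[0] == res.labels[1].rsplit("_", 1)[0]
    ]
    return GxEScanResult(
        vc=vc,
        pairs=pairs,
        h2=h2,
        alpha=alpha,
        n_traits=n_traits,
        threshold=threshold,
        dropped_groups=dropped,
        sex_contrast_pairs=sex_pairs,
    )


def sex_stratified_scan(
    cohort: pd.DataFrame,
    grm: GRM,
    alpha: float = 0.05,
    n_traits: int = 1,
    min_group: int = 50,
    **kwargs,
) -> GxEScanResult:
    """Eight-group scan (environment x sex).  Within-environment male/female
    contrasts are flagged separately in ``sex_contrast_pairs``; groups
    missing a sex (below the floor) are dropped with a warning."""
    return gxe_scan(
        cohort,
        grm,
        mode="eight_group_by_sex",
        alpha=alpha,
        n_traits=n_traits,
        min_group=min_group,
        **kwargs,
    )


@dataclass
class PermutationResult:
    observed: float  # observed r_G
    statistic: float  # |r_G - 1|
    p_value: float
    null_r_g: np.ndarray
    n_perm: int
    n_failed: int


def permutation_test(
    cohort: pd.DataFrame,
    grm: GRM,
    pair: tuple,
    n_perm: int = 1000,
    seed: int | None = None,
    pheno_col: str = "phenotype",
    group_col: str = "group",
    max_retry_factor: float = 0.2,
    **fit_kwargs,
) -> PermutationResult:
    """Permutation null for one environment contrast.

    Environment labels of the two groups are shuffled jointly, keeping the
    two group sizes exactly as observed; each shuffle is refitted with a
    bivariate GREML and the statistic |r_hat_G - 1| (deviation from the
    no-G-by-E null) recomputed.  The empirical p-value uses the add-one
    estimator (1 + #{null >= observed}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1).  Non-convergent shuffles are redrawn
    up to a retry cap; if more than 20% of fits fail the test aborts.
    """
    g1, g2 = pair
    sub = cohort[cohort[group_col].isin([g1, g2])].reset_index(drop=True)
    n1 = int((sub[group_col] == g1).sum())
    n2 = int((sub[group_col] == g2).sum())
    if n1 == 0 or n2 == 0:
        raise DomainError(f"pair {pair} not present in cohort")
    rng = np.random.default_rng(seed)

    fit_kwargs.setdefault("on_fail", "raise")

    def _rg(frame, theta0=None):
        blocks = ModelBlocks.from_cohort(
            frame, grm, group_col=group_col, pheno_col=pheno_col, groups=[g1, g2]
        )
        vc = reml_fit(blocks, grm, mode="gxe", theta0=theta0, **fit_kwargs)
        ki = vc.param_index("g", 0, 0, 0)
        kj = vc.param_index("g", 0, 1, 1)
        kc = vc.param_index("g", 0, 0, 1)
        if vc.boundary[ki] or vc.boundary[kj]:
            raise BoundaryError("genetic variance at floor; r_G undefined")
        v1, v2, c = vc.params[ki], vc.params[kj], vc.params[kc]
        return float(c / np.sqrt(v1 * v2)), vc.params

    observed, theta_hat = _rg(sub)
    stat_obs = abs(observed - 1.0)

    labels = np.array([g1] * n1 + [g2] * n2, dtype=object)
    null = np.empty(n_perm)
    n_failed = 0
    max_failures = int(np.ceil(max_retry_factor * n_perm))
    k = 0
    while k < n_perm:
        perm = sub.copy()
        perm[group_col] = rng.permutation(labels)
        try:
            rg, _ = _rg(perm, theta0=theta_hat)
        except (ConvergenceError, EnvGremlError):
            # one redraw with a cold start before counting a failure
            try:
                perm[group_col] = rng.permutation(labels)
                rg, _ = _rg(perm)
            except (ConvergenceError, EnvGremlError):
                n_failed += 1
                if n_failed > max_failures:
                    raise ConvergenceError(
                        f"more than {max_retry_factor:.0%} of permutation fits "
                        "failed to converge"
                    )
                continue
        null[k] = rg
        k += 1

    stat_null = np.abs(null - 1.0)
    p = (1.0 + np.sum(stat_null >= stat_obs)) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed,
        statistic=stat_obs,
        p_value=float(p),
        null_r_g=null,
        n_perm=n_perm,
        n_failed=n_failed,
    )
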