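"""Multivariate GREML: average-information REML for variance components.

The model stacks K blocks (environment groups in G-by-E mode, traits in
multi-trait mode):

    y_i = X_i b_i + Z_i g_i + e_i,    i = 1..K

with var(g) built from one or more genomic relationship matrices A and a
K x K genetic covariance per GRM component.  The phenotypic covariance is

    V[i, j] = sum_c  sigma_g_c[i, j] * A_c[idx_i, idx_j]  +  R[i, j]

where the residual R is block-diagonal (I * sigma_e_i) in G-by-E mode --
disjoint individuals have no repeated measures, so residual covariance is
structurally zero -- and additionally carries sigma_e_ij on the entries
where blocks i and j share individuals in multi-trait mode.

Estimation maximizes the restricted likelihood

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1

by average-information updates with an EM warm-up first step and
step-halving whenever a proposal would decrease logL.  The AI matrix at
convergence serves as the information matrix for delta-method standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import lapack

from .exceptions import (
    BoundaryError,
    ConvergenceError,
    DimensionError,
    DomainError,
    ModelError,
)
from .grm import GRM


# ---------------------------------------------------------------------------
# model assembly


@dataclass
class ModelBlocks:
    """Per-block phenotype, fixed-effect design and GRM sample index.

    ``idx[i]`` maps block i's rows to rows of the GRM(s); in G-by-E mode
    the index sets of distinct blocks must be disjoint.
    """

    y: list
    idx: list
    X: list | None = None
    labels: list | None = None

    def __post_init__(self):
        self.y = [np.asarray(v, dtype=float).ravel() for v in self.y]
        self.idx = [np.asarray(v, dtype=int).ravel() for v in self.idx]
        if len(self.y) != len(self.idx):
            raise DimensionError("y and idx must have one entry per block")
        if self.X is None:
            self.X = [np.ones((len(v), 1)) for v in self.y]
        for i, (yv, xv, ix) in enumerate(zip(self.y, self.X, self.idx)):
            if len(yv) != xv.shape[0] or len(yv) != len(ix):
                raise DimensionError(f"block {i}: y/X/idx length mismatch")
            if len(yv) <= np.linalg.matrix_rank(xv):
                raise DimensionError(f"block {i}: n must exceed rank(X)")
        if self.labels is None:
            self.labels = [f"block{i + 1}" for i in range(len(self.y))]

    @property
    def K(self) -> int:
        return len(self.y)

    @property
    def sizes(self) -> list:
        return [len(v) for v in self.y]

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        grm: GRM,
        group_col: str = "group",
        pheno_col: str = "phenotype",
        groups=None,
    ) -> "ModelBlocks":
        """Build disjoint G-by-E blocks from a cohort table (one row per
        sample, ``sample_id`` matching the GRM ids)."""
        if groups is None:
            groups = sorted(cohort[group_col].dropna().unique())
        y, idx = [], []
        for g in groups:
            sub = cohort[cohort[group_col] == g]
            y.append(sub[pheno_col].to_numpy(dtype=float))
            idx.append(grm.index_of(sub["sample_id"]))
        return cls(y=y, idx=idx, labels=list(groups))


class _Param:
    """One free variance parameter with its non-zero block structure."""

    def __init__(self, kind, comp, i, j, sub=None, pairs=None, offsets=None, sizes=None):
        self.kind = kind  # 'g' or 'e'
        self.comp = comp  # GRM index for 'g', None for 'e'
        self.i, self.j = i, j
        self.sub = sub  # A_c[idx_i, idx_j] for 'g'
        self.pairs = pairs  # (rows_i, rows_j) for residual covariance
        self.off = offsets
        self.sizes = sizes

    @property
    def is_variance(self) -> bool:
        return self.i == self.j

    def _slices(self):
        si = slice(self.off[self.i], self.off[self.i] + self.sizes[self.i])
        sj = slice(self.off[self.j], self.off[self.j] + self.sizes[self.j])
        return si, sj

    def add_to(self, V, theta):
        si, sj = self._slices()
        if self.kind == "g":
            if self.i == self.j:
                V[si, si] += theta * self.sub
            else:
                V[si, sj] += theta * self.sub
                V[sj, si] += theta * self.sub.T
        else:
            if self.i == self.j:
                V[si, si] += theta * np.eye(self.sizes[self.i])
            else:
                ri, rj = self.pairs
                V[self.off[self.i] + ri, self.off[self.j] + rj] += theta
                V[self.off[self.j] + rj, self.off[self.i] + ri] += theta

    def matvec(self, x):
        """V_k @ x for the unit-theta structure matrix."""
        out = np.zeros_like(x)
        si, sj = self._slices()
        if self.kind == "g":
            if self.i == self.j:
                out[si] = self.sub @ x[si]
            else:
                out[si] = self.sub @ x[sj]
                out[sj] = self.sub.T @ x[si]
        else:
            if self.i == self.j:
                out[si] = x[si]
            else:
                ri, rj = self.pairs
                out[self.off[self.i] + ri] += x[self.off[self.j] + rj]
                out[self.off[self.j] + rj] += x[self.off[self.i] + ri]
        return out

    def ddot(self, P):
        """tr(P V_k) exploiting the sparsity pattern of V_k."""
        si, sj = self._slices()
        if self.kind == "g":
            if self.i == self.j:
                return float(np.sum(P[si, si] * self.sub))
            return 2.0 * float(np.sum(P[si, sj] * self.sub))
        if self.i == self.j:
            return float(np.trace(P[si, si]))
        ri, rj = self.pairs
        return 2.0 * float(P[self.off[self.i] + ri, self.off[self.j] + rj].sum())


@dataclass
class VarianceComponents:
    """REML estimates: per-component genetic covariance matrices, residual
    (co)variances, restricted log-likelihood and the information matrix."""

    sigma_g: list  # one K x K matrix per GRM component
    sigma_e: np.ndarray  # K x K (diagonal in G-by-E mode)
    logl: float
    info: np.ndarray
    params: np.ndarray
    param_names: list  # (kind, comp, i, j)
    n_iter: int
    converged: bool
    boundary: np.ndarray
    block_labels: list
    block_sizes: list
    mode: str
    floors: np.ndarray
    logl_trail: list = field(default_factory=list)
    grm_labels: list | None = None

    @property
    def K(self) -> int:
        return len(self.block_labels)

    @property
    def n_components(self) -> int:
        return len(self.sigma_g)

    def param_index(self, kind, comp, i, j) -> int:
        if i > j:
            i, j = j, i
        key = (kind, comp if kind == "g" else None, i, j)
        return self.param_names.index(key)

    @property
    def identifiable(self) -> bool:
        """Whether the information matrix supports standard errors."""
        try:
            cond = np.linalg.cond(self.info)
        except np.linalg.LinAlgError:
            return False
        return bool(np.isfinite(cond) and cond < 1e10)

    def param_cov(self) -> np.ndarray | None:
        """Asymptotic covariance of the estimates (inverse information),
        or None when the fit is not identifiable."""
        if not self.identifiable:
            return None
        return np.linalg.inv(self.info)

    def total_sigma_g(self) -> np.ndarray:
        return np.sum(self.sigma_g, axis=0)

    def h2(self, i: int, with_se: bool = True):
        """SNP heritability of block i: total genetic variance over total
        phenotypic variance, delta-method SE and two-sided Wald p vs 0."""
        vg = float(self.total_sigma_g()[i, i])
        ve = float(self.sigma_e[i, i])
        tot = vg + ve
        est = vg / tot
        if not with_se:
            return est, np.nan, np.nan
        C = self.param_cov()
        if C is None:
            return est, np.nan, np.nan
        ks = [self.param_index("g", c, i, i) for c in range(self.n_components)]
        ke = self.param_index("e", None, i, i)
        grad = np.zeros(len(self.params))
        for k in ks:
            grad[k] = ve / tot**2
        grad[ke] = -vg / tot**2
        var = float(grad @ C @ grad)
        se = np.sqrt(var) if var > 0 else np.nan
        p = wald_test(est, se, 0.0) if np.isfinite(se) and se > 0 else np.nan
        return est, se, p


def _build_params(blocks: ModelBlocks, grms: list, mode: str):
    K = blocks.K
    offsets = np.concatenate([[0], np.cumsum(blocks.sizes)])[:-1]
    sizes = blocks.sizes
    params, names = [], []
    for c, grm in enumerate(grms):
        for i in range(K):
            for j in range(i, K):
                sub = grm.values[np.ix_(blocks.idx[i], blocks.idx[j])]
                params.append(
                    _Param("g", c, i, j, sub=sub, offsets=offsets, sizes=sizes)
                )
                names.append(("g", c, i, j))
    for i in range(K):
        params.append(_Param("e", None, i, i, offsets=offsets, sizes=sizes))
        names.append(("e", None, i, i))
    if mode == "multi_trait":
        for i in range(K):
            look = {s: a for a, s in enumerate(blocks.idx[i])}
            for j in range(i + 1, K):
                ri, rj = [], []
                for b, s in enumerate(blocks.idx[j]):
                    a = look.get(s)
                    if a is not None:
                        ri.append(a)
                        rj.append(b)
                if ri:
                    params.append(
                        _Param(
                            "e", None, i, j,
                            pairs=(np.array(ri), np.array(rj)),
                            offsets=offsets, sizes=sizes,
                        )
                    )
                    names.append(("e", None, i, j))
    else:
        # disjoint blocks required in G-by-E mode
        seen = set()
        for ix in blocks.idx:
            s = set(ix.tolist())
            if seen & s:
                raise ModelError(
                    "G-by-E mode requires disjoint sample sets across blocks"
                )
            seen |= s
    return params, names


def _reml_state(theta, params, N, X, y):
    """(logl, P, Py) at theta, or None when V is not positive definite."""
    V = np.zeros((N, N))
    for th, pr in zip(theta, params):
        pr.add_to(V, th)
    c, info = lapack.dpotrf(V, lower=1)
    if info != 0:
        return None
    d = np.diag(c)
    # numerically singular V (possible when an indefinite genetic covariance
    # cancels the residual on a rank-deficient GRM) corrupts the restricted
    # likelihood through the log-determinant; treat it as infeasible
    if (d.min() / d.max()) ** 2 < 1e-9:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vinv, info2 = lapack.dpotri(c, lower=1)
    if info2 != 0:
        return None
    vinv = np.tril(vinv) + np.tril(vinv, -1).T
    vix = vinv @ X
    xtvix = X.T @ vix
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return None
    try:
        beta_part = np.linalg.solve(xtvix, vix.T)
    except np.linalg.LinAlgError:
        return None
    P = vinv - vix @ beta_part
    Py = P @ y
    logl = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return logl, P, Py


def reml_fit(
    blocks: ModelBlocks,
    grms,
    mode: str = "gxe",
    max_iter: int = 100,
    tol: float = 1e-6,
    em_first: bool = True,
    variance_floor_scale: float = 1e-6,
    theta0: np.ndarray | None = None,
    on_fail: str = "raise",
) -> VarianceComponents:
    """Fit the multivariate GREML model by AI-REML.

    Parameters
    ----------
    blocks : phenotypes, designs and GRM indices per block.
    grms : a GRM or list of GRMs (multiple GRMs partition the genetic
        variance across SNP categories; one genetic covariance matrix is
        fitted per GRM with a shared residual structure).
    mode : 'gxe' (disjoint groups, residual covariance fixed at 0) or
        'multi_trait' (possibly overlapping samples, residual covariance
        estimated where samples overlap).
    tol : convergence on |delta logL|.
    theta0 : optional start values (warm start, e.g. in permutations).
    on_fail : 'raise' a ConvergenceError or 'flag' (return converged=False).
    """
    if mode not in ("gxe", "multi_trait"):
        raise DomainError(f"mode must be 'gxe' or 'multi_trait', got {mode!r}")
    if isinstance(grms, GRM):
        grms = [grms]
    grms = list(grms)
    K = blocks.K
    n_comp = len(grms)
    params, names = _build_params(blocks, grms, mode)
    q = len(params)
    N = sum(blocks.sizes)
    y = np.concatenate(blocks.y)
    offsets = np.concatenate([[0], np.cumsum(blocks.sizes)])[:-1]
    p_fixed = sum(x.shape[1] for x in blocks.X)
    X = np.zeros((N, p_fixed))
    col = 0
    for i, xb in enumerate(blocks.X):
        X[offsets[i]:offsets[i] + blocks.sizes[i], col:col + xb.shape[1]] = xb
        col += xb.shape[1]

    vary = np.array([np.var(b) for b in blocks.y])
    if (vary <= 0).any():
        raise ModelError("constant phenotype in some block")
    floors = np.zeros(q)
    is_var = np.zeros(q, dtype=bool)
    block_of = np.zeros(q, dtype=int)
    for k, (kind, comp, i, j) in enumerate(names):
        block_of[k] = i
        if i == j:
            is_var[k] = True
            floors[k] = variance_floor_scale * vary[i]

    if theta0 is None:
        theta = np.zeros(q)
        for k, (kind, comp, i, j) in enumerate(names):
            if i == j:
                theta[k] = vary[i] / 2.0 / (n_comp if kind == "g" else 1.0)
    else:
        theta = np.asarray(theta0, dtype=float).copy()
        if theta.shape != (q,):
            raise DimensionError(f"theta0 must have length {q}")
    theta = np.where(is_var, np.maximum(theta, floors), theta)

    state = _reml_state(theta, params, N, X, y)
    if state is None:
        raise ModelError("starting V matrix is not positive definite")
    logl, P, Py = state
    trail = [logl]
    converged = False
    n_iter = 0
    ai = np.eye(q)

    for it in range(1, max_iter + 1):
        n_iter = it
        w = np.column_stack([pr.matvec(Py) for pr in params])  # N x q
        ypvpy = w.T @ Py  # y'P V_k P y
        trpv = np.array([pr.ddot(P) for pr in params])
        score = 0.5 * (ypvpy - trpv)
        pw = P @ w
        ai = 0.5 * (w.T @ pw)
        ai = 0.5 * (ai + ai.T)

        def _try_direction(delta, n_halvings=20):
            step = 1.0
            for _ in range(n_halvings):
                cand = theta + step * delta
                cand = np.where(is_var, np.maximum(cand, floors), cand)
                st = _reml_state(cand, params, N, X, y)
                if st is not None and st[0] >= logl - 1e-10:
                    return cand, st
                step *= 0.5
            return None

        accepted = None
        if it == 1 and em_first and theta0 is None:
            # generalized EM update on variance parameters; covariances
            # (starting at 0) are held for the warm-up step
            delta = np.zeros(q)
            for k in range(q):
                if is_var[k]:
                    nk = blocks.sizes[block_of[k]]
                    delta[k] = theta[k] ** 2 / nk * (ypvpy[k] - trpv[k])
            accepted = _try_direction(delta)
        else:
            # active-set AI step: parameters pinned at their floor with an
            # outward-pointing gradient are frozen so clipped coordinates do
            # not pollute the direction; Levenberg-Marquardt damping falls
            # back toward the gradient when the undamped AI direction fails
            # (AI can be ill-conditioned near the positive-definite boundary)
            pinned = is_var & (theta <= floors * (1 + 1e-6)) & (score < 0)
            free = ~pinned
            damp = np.diag(np.maximum(np.abs(np.diag(ai)), 1e-8))
            for lam in (0.0, 0.01, 0.1, 1.0, 10.0, 100.0):
                delta = np.zeros(q)
                try:
                    a_sub = (ai + lam * damp)[np.ix_(free, free)]
                    delta[free] = np.linalg.solve(a_sub, score[free])
                except np.linalg.LinAlgError:
                    continue
                if not np.all(np.isfinite(delta)):
                    continue
                accepted = _try_direction(delta)
                if accepted is not None:
                    break
        if accepted is None:
            # no ascent direction found: already at a (numerical) optimum
            converged = True
            break
        theta, (new_logl, P, Py) = accepted
        trail.append(new_logl)
        if abs(new_logl - logl) < tol:
            logl = new_logl
            converged = True
            break
        logl = new_logl

    if not converged and on_fail == "raise":
        raise ConvergenceError(
            f"AI-REML did not converge in {n_iter} iterations "
            f"(last |dlogL|={abs(trail[-1] - trail[-2]) if len(trail) > 1 else np.nan:.3e})",
            logl_trail=trail,
        )

    # information matrix at the optimum
    w = np.column_stack([pr.matvec(Py) for pr in params])
    ai = 0.5 * (w.T @ (P @ w))
    ai = 0.5 * (ai + ai.T)

    sigma_g = [np.zeros((K, K)) for _ in range(n_comp)]
    sigma_e = np.zeros((K, K))
    for k, (kind, comp, i, j) in enumerate(names):
        if kind == "g":
            sigma_g[comp][i, j] = sigma_g[comp][j, i] = theta[k]
        else:
            sigma_e[i, j] = sigma_e[j, i] = theta[k]

    boundary = is_var & (theta <= floors * (1 + 1e-6) + 1e-300)
    return VarianceComponents(
        sigma_g=sigma_g,
        sigma_e=sigma_e,
        logl=float(logl),
        info=ai,
        params=theta,
        param_names=names,
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        block_labels=list(blocks.labels),
        block_sizes=list(blocks.sizes),
        mode=mode,
        floors=floors,
        logl_trail=trail,
        grm_labels=[f"grm{c + 1}" for c in range(n_comp)],
    )


# ---------------------------------------------------------------------------
# inference on the fitted components


def wald_test(estimate: float, se: float, null_value: float = 0.0) -> float:
    """Two-sided normal-approximation p-value for estimate vs null."""
    if not np.isfinite(se) or se <= 0:
        raise DomainError(f"standard error must be positive, got {se}")
    z = abs(estimate - null_value) / se
    return float(2.0 * stats.norm.sf(z))


@dataclass(frozen=True)
class GeneticCorrelationResult:
    """Cross-block genetic correlation with delta-method inference."""

    pair: tuple
    labels: tuple
    r_g: float
    se: float
    p_vs_0: float
    p_vs_1: float
    h2_i: float
    h2_i_se: float
    h2_j: float
    h2_j_se: float


def genetic_correlation(
    vc: VarianceComponents, i: int, j: int, component: int = 0
) -> GeneticCorrelationResult:
    """r_G between blocks i and j: genetic covariance over the geometric
    mean of the genetic variances, with first-order delta-method SE from
    the inverse information matrix and two-sided Wald tests against 0
    (shared genetics) and 1 (no G-by-E).

    The estimate is unconstrained and may exceed 1 in magnitude.
    """
    if i == j:
        raise DomainError("need two distinct blocks")
    if not vc.converged:
        raise ConvergenceError("fit did not converge; r_G inference unavailable")
    ki = vc.param_index("g", component, i, i)
    kj = vc.param_index("g", component, j, j)
    kc = vc.param_index("g", component, i, j)
    v1, v2, cov = vc.params[ki], vc.params[kj], vc.params[kc]
    if vc.boundary[ki] or vc.boundary[kj]:
        raise BoundaryError(
            f"genetic variance at its floor for block {i if vc.boundary[ki] else j}; "
            "r_G undefined"
        )
    rg = cov / np.sqrt(v1 * v2)
    C = vc.param_cov()
    if C is None:
        raise BoundaryError(
            "information matrix is singular (non-identifiable fit); "
            "no standard error can be reported"
        )
    grad = np.zeros(len(vc.params))
    grad[ki] = -rg / (2.0 * v1)
    grad[kj] = -rg / (2.0 * v2)
    grad[kc] = 1.0 / np.sqrt(v1 * v2)
    var = float(grad @ C @ grad)
    se = float(np.sqrt(var)) if var > 0 else np.nan
    p0 = wald_test(rg, se, 0.0) if np.isfinite(se) and se > 0 else np.nan
    p1 = wald_test(rg, se, 1.0) if np.isfinite(se) and se > 0 else np.nan
    h2i, h2i_se, _ = vc.h2(i)
    h2j, h2j_se, _ = vc.h2(j)
    return GeneticCorrelationResult(
        pair=(i, j),
        labels=(vc.block_labels[i], vc.block_labels[j]),
        r_g=float(rg),
        se=se,
        p_vs_0=p0,
        p_vs_1=p1,
        h2_i=h2i,
        h2_i_se=h2i_se,
        h2_j=h2j,
        h2_j_se=h2j_se,
    )


@dataclass(frozen=True)
class PartitionRatioResult:
    """Share of genetic (co)variance attributed to one GRM component."""

    component: int
    i: int
    j: int
    ratio: float
    se: float
    snp_fraction: float | None
    p_vs_fraction: float | None


def partition_ratio(
    vc: VarianceComponents,
    component: int,
    i: int = 0,
    j: int | None = None,
    snp_fraction: float | None = None,
) -> PartitionRatioResult:
    """Ratio of the genetic variance (j = i) or covariance (j != i) of the
    chosen GRM component over the sum across components, with delta-method
    SE and a one-sided test that the ratio exceeds the component's share
    of SNPs (enrichment)."""
    if vc.n_components < 2:
        if vc.n_components == 1 and component == 0:
            return PartitionRatioResult(component, i, i if j is None else j,
                                        1.0, 0.0, snp_fraction, None)
        raise DomainError("partitioning needs a multi-GRM fit")
    j = i if j is None else j
    if j < i:
        i, j = j, i
    ks = [vc.param_index("g", c, i, j) for c in range(vc.n_components)]
    vals = vc.params[ks]
    total = vals.sum()
    floor_tot = vc.floors[ks].sum()
    if i == j and total <= floor_tot * (1 + 1e-6):
        raise BoundaryError("total genetic variance at its floor; ratio undefined")
    ratio = float(vals[component] / total)
    C = vc.param_cov()
    se = np.nan
    if C is not None:
        grad = np.zeros(len(vc.params))
        for c, k in enumerate(ks):
            grad[k] = (1.0 if c == component else 0.0) / total - vals[component] / total**2
        var = float(grad @ C @ grad)
        se = float(np.sqrt(var)) if var > 0 else np.nan
    p = None
    if snp_fraction is not None and np.isfinite(se) and se > 0:
        p = float(stats.norm.sf((ratio - snp_fraction) / se))
    return PartitionRatioResult(component, i, j, ratio, se, snp_fraction, p)
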