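"""Closed-form quantitative genetics of truncation selection.

A standardized trait y = g + e with g ~ N(0, h2) and e ~ N(0, 1 - h2) is
subjected to interval truncation: individuals with t1 < s < t2 are kept,
where the selection variable s is either y itself (direct selection) or a
variable with phenotypic correlation r to y (selection on a correlated
environmental variable).  With K_j = P(y > t_j) the upper-tail proportion
and i_j = phi(t_j)/K_j the selection intensity, the selected-sample
moments have closed forms; the key identity is that the genetic values of
the selected sample satisfy g_s = c + b g, so a genetic correlation
between two independently truncated groups is unchanged:

    cor(g_s1, g_s2) = b1 b2 cov(g1, g2) / (b1 sd(g1) b2 sd(g2)) = cor(g1, g2),

i.e. ascertainment by truncation cannot create spurious G-by-E.

For selection on a correlated variable the published mean formula sets
E(g_s) = 0 on the assumption that the correlation is purely environmental;
under the standard bivariate-normal construction s = r y + sqrt(1-r^2) eps
the mean is r h2 E(s | selected) instead, while the published second
moment E(g_s^2) is exact under that construction.  The default here
returns the internally consistent set (mean retained); ``as_printed=True``
reproduces the published formulas verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DomainError


def _phi(t: float) -> float:
    return 0.0 if math.isinf(t) else float(stats.norm.pdf(t))


def _phi_t(t: float) -> float:
    """phi(t) * t with the limit convention 0 at +-infinity."""
    return 0.0 if math.isinf(t) else float(stats.norm.pdf(t)) * t


def truncation_constants(t1: float, t2: float) -> tuple[float, float, float, float]:
    """Upper-tail proportions and selection intensities (K1, K2, i1, i2)
    for thresholds ``t1 < t2`` on the standard-normal scale.

    K_j = 1 - Phi(t_j); i_j = phi(t_j)/K_j with K_j i_j -> 0 as t -> +-inf
    (i is reported as 0 where K = 0 or the density vanishes).
    """
    if not t1 < t2:
        raise DomainError(f"thresholds must satisfy t1 < t2, got {t1} >= {t2}")
    out = []
    for t in (t1, t2):
        K = float(stats.norm.sf(t))
        phi = _phi(t)
        i = phi / K if K > 0 else 0.0
        out.extend([K, i])
    K1, i1, K2, i2 = out
    return K1, K2, i1, i2


@dataclass(frozen=True)
class SelectionRegime:
    """Interval truncation t1 < s < t2 on a standardized selection variable
    with correlation ``r`` to the trait (r = 1: direct selection on y)."""

    t1: float
    t2: float
    h2: float
    r: float = 1.0

    def __post_init__(self):
        if not self.t1 < self.t2:
            raise DomainError(f"need t1 < t2, got ({self.t1}, {self.t2})")
        if not 0 <= self.h2 <= 1:
            raise DomainError(f"h2 must be in [0, 1], got {self.h2}")
        if not -1 <= self.r <= 1:
            raise DomainError(f"r must be in [-1, 1], got {self.r}")

    @property
    def constants(self) -> tuple[float, float, float, float]:
        return truncation_constants(self.t1, self.t2)

    @property
    def selected_proportion(self) -> float:
        K1, K2, _, _ = self.constants
        return K1 - K2  # P(t1 < s < t2)


@dataclass(frozen=True)
class SelectionMoments:
    """Post-selection moments: selected phenotype mean/variance, selected
    genetic-value mean/variance, realized heritability, and the affine
    coefficients of g_s = c + b g."""

    mean_y_s: float
    var_y_s: float
    mean_g_s: float
    var_g_s: float
    h2_s: float
    b: float
    c: float

    def as_dict(self) -> dict:
        return {
            "mean_y_s": self.mean_y_s,
            "var_y_s": self.var_y_s,
            "mean_g_s": self.mean_g_s,
            "var_g_s": self.var_g_s,
            "h2_s": self.h2_s,
            "b": self.b,
            "c": self.c,
        }


def _qm(regime: SelectionRegime) -> tuple[float, float, float]:
    """(K2-K1, truncated mean m, quadratic term Q) with infinite-threshold
    limits handled through phi(t), phi(t)*t -> 0."""
    t1, t2 = regime.t1, regime.t2
    K1, K2, _, _ = regime.constants
    kd = K2 - K1
    if kd == 0:
        raise DomainError("degenerate truncation region: zero selected proportion")
    m = (_phi(t2) - _phi(t1)) / kd
    Q = (_phi_t(t2) - _phi_t(t1)) / kd
    return kd, m, Q


def post_selection_moments(regime: SelectionRegime) -> SelectionMoments:
    """Moments under direct interval truncation on the phenotype (r = 1):

        E(y_s)   = (K2 i2 - K1 i1) / (K2 - K1)
        var(y_s) = 1 + Q - E(y_s)^2,  Q = (K2 i2 t2 - K1 i1 t1)/(K2 - K1)
        E(g_s)   = h2 E(y_s)
        var(g_s) = h2 [1 + h2 (Q - E(y_s)^2)]
        h2_s     = var(g_s) / var(y_s),  b = sqrt(var(g_s) / h2)
    """
    if regime.r != 1.0:
        raise DomainError("direct-selection moments require r = 1; "
                          "use correlated_selection_moments")
    _, m, Q = _qm(regime)
    h2 = regime.h2
    var_y = 1.0 + Q - m * m
    if var_y <= 0:
        raise DomainError("degenerate selection region: non-positive variance")
    mean_g = h2 * m
    var_g = h2 * (1.0 + h2 * (Q - m * m))
    return SelectionMoments(
        mean_y_s=m,
        var_y_s=var_y,
        mean_g_s=mean_g,
        var_g_s=var_g,
        h2_s=var_g / var_y,
        b=math.sqrt(max(var_g / h2, 0.0)) if h2 > 0 else 1.0,
        c=mean_g,
    )


def correlated_selection_moments(
    regime: SelectionRegime, as_printed: bool = False
) -> SelectionMoments:
    """Moments when selection acts on a variable with correlation r to the
    trait (bivariate-normal construction s = r y + sqrt(1-r^2) eps):

        E(y_s)   = r m,           var(y_s) = 1 + r^2 (Q - m^2)
        E(g_s^2) = h2 (1 + h2 r^2 Q)

    Default (internally consistent): E(g_s) = r h2 m and
    var(g_s) = E(g_s^2) - E(g_s)^2.  With ``as_printed=True`` the published
    convention E(g_s) = 0 is used, so var(g_s) = E(g_s^2) and h2_s omits
    the mean correction; both share E(y_s), var(y_s) and E(g_s^2).
    """
    _, m, Q = _qm(regime)
    h2, r = regime.h2, regime.r
    r2 = r * r
    mean_y = r * m
    var_y = 1.0 + r2 * (Q - m * m)
    if var_y <= 0:
        raise DomainError("degenerate selection region: non-positive variance")
    eg2 = h2 * (1.0 + h2 * r2 * Q)
    if as_printed:
        mean_g, var_g = 0.0, eg2
    else:
        mean_g = r * h2 * m
        var_g = eg2 - mean_g * mean_g
    return SelectionMoments(
        mean_y_s=mean_y,
        var_y_s=var_y,
        mean_g_s=mean_g,
        var_g_s=var_g,
        h2_s=var_g / var_y,
        b=math.sqrt(max(var_g / h2, 0.0)) if h2 > 0 else 1.0,
        c=mean_g,
    )


class RgUnderSelection(NamedTuple):
    r_g: float
    b1: float
    b2: float


def rg_under_selection(
    r_g: float, regime_1: SelectionRegime, regime_2: SelectionRegime
) -> RgUnderSelection:
    """Genetic correlation between two independently truncated groups.

    Because g_s = c + b g within each group, cov scales by b1 b2 and each
    sd by b: the correlation is exactly the pre-selection ``r_g``.  The
    two b factors are returned for reporting.
    """
    if not -1 <= r_g <= 1:
        raise DomainError(f"|r_G| must be <= 1, got {r_g}")

    def _b(reg: SelectionRegime) -> float:
        mom = (
            post_selection_moments(reg)
            if reg.r == 1.0
            else correlated_selection_moments(reg)
        )
        return mom.b

    return RgUnderSelection(r_g=r_g, b1=_b(regime_1), b2=_b(regime_2))


def monte_carlo_moments(
    regime: SelectionRegime, n_draws: int = 1_000_000, seed: int | None = None
) -> tuple[SelectionMoments, dict, int]:
    """Simulation counterpart of the closed forms (independent check).

    Draws (g, e), forms y = g + e and the selection variable, truncates,
    and returns empirical moments together with approximate standard
    errors of each moment and the selected count.
    """
    rng = np.random.default_rng(seed)
    h2 = regime.h2
    g = rng.normal(0.0, math.sqrt(h2), n_draws)
    e = rng.normal(0.0, math.sqrt(1.0 - h2), n_draws)
    y = g + e
    if regime.r == 1.0:
        s = y
    else:
        s = regime.r * y + math.sqrt(1.0 - regime.r**2) * rng.normal(size=n_draws)
    keep = (s > regime.t1) & (s < regime.t2)
    ns = int(keep.sum())
    if ns < 2:
        raise DomainError("selection region retained fewer than 2 draws")
    ys, gs = y[keep], g[keep]
    var_y, var_g = ys.var(), gs.var()
    mom = SelectionMoments(
        mean_y_s=float(ys.mean()),
        var_y_s=float(var_y),
        mean_g_s=float(gs.mean()),
        var_g_s=float(var_g),
        h2_s=float(var_g / var_y),
        b=float(math.sqrt(var_g / h2)) if h2 > 0 else 1.0,
        c=float(gs.mean()),
    )
    # moment SEs: mean ~ sd/sqrt(n); variance of sample variance via 4th moment
    def _var_se(x):
        xc = x - x.mean()
        m4 = np.mean(xc**4)
        v = x.var()
        return math.sqrt(max(m4 - v * v, 0.0) / len(x))

    se = {
        "mean_y_s": float(ys.std() / math.sqrt(ns)),
        "mean_g_s": float(gs.std() / math.sqrt(ns)),
        "var_y_s": _var_se(ys),
        "var_g_s": _var_se(gs),
    }
    # h2_s and b are smooth functions of the above; propagate crudely
    se["h2_s"] = mom.h2_s * math.sqrt(
        (se["var_g_s"] / max(var_g, 1e-12)) ** 2
        + (se["var_y_s"] / max(var_y, 1e-12)) ** 2
    )
    se["b"] = 0.5 * se["var_g_s"] / math.sqrt(max(var_g * h2, 1e-12)) if h2 > 0 else 0.0
    se["c"] = se["mean_g_s"]
    return mom, se, ns
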