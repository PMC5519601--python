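"""Phenotype preparation: covariate adjustment, rank-based inverse normal
transformation and environment stratification.

The workflow mirrors standard biobank practice: phenotypes are adjusted by
OLS for confounders (sex, year of birth, batch, principal components ...)
on the full sample, optionally inverse-normal transformed, and only then
stratified into environment groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ModelError

#: canonical four-environment labels: breastfed x maternal smoking
FOUR_GROUPS = ("B&NS", "B&S", "NB&NS", "NB&S")


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Build an OLS design with intercept; factor/object columns one-hot
    encoded with the first level as reference."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
                names.append(dname)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def adjust_phenotype(
    y, covariates: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.Index]:
    """OLS-residual phenotype after regressing out fixed covariates.

    Returns ``(residuals, dropped_index)``; rows with missing phenotype or
    covariates are dropped (listwise) and reported.  With no covariates the
    result is the mean-centred phenotype.
    """
    y = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y.astype(float)
    if covariates is None or covariates.shape[1] == 0:
        ok = y.notna()
        res = y[ok] - y[ok].mean()
        return res, y.index[~ok]

    covariates = covariates.loc[y.index]
    ok = y.notna() & covariates.notna().all(axis=1)
    dropped = y.index[~ok]
    yv = y[ok].to_numpy()
    X, names = _design_matrix(covariates[ok])
    if len(yv) <= X.shape[1]:
        raise ModelError(
            f"n={len(yv)} samples cannot support {X.shape[1]} design columns"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a maximal independent subset greedily
        keep, basis = [], np.zeros((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([basis, X[:, j]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep.append(j)
                basis = cand
        aliased = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear design columns: {aliased}")
        X = X[:, keep]
        names = [names[j] for j in keep]
        if X.shape[1] == 0 or np.linalg.matrix_rank(X) < X.shape[1]:
            raise ModelError(f"design rank-deficient; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    res = pd.Series(yv - X @ beta, index=y.index[ok])
    return res, dropped


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default):

        v -> Phi^{-1}((rank(v) - c) / (n + 1 - 2c)),  c = 3/8

    Ties receive average ranks; the mapping preserves ordering.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DomainError("need a 1-D vector with at least 2 values")
    if not np.isfinite(v).all():
        raise DomainError("values must be finite")
    if np.ptp(v) == 0:
        raise DomainError("all values identical; transform degenerate")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size + 1 - 2 * offset))


def standardize_within_group(
    cohort: pd.DataFrame,
    pheno_col: str = "phenotype",
    group_col: str = "group",
) -> pd.Series:
    """Zero-mean/unit-variance phenotype within each group.

    Optional: per-group standardization rescales each group's variance
    components by the same factor and therefore leaves the cross-group
    genetic correlation unchanged.
    """
    def _z(x):
        sd = x.std(ddof=0)
        if sd == 0:
            raise DomainError(f"constant phenotype in a group")
        return (x - x.mean()) / sd

    return cohort.groupby(group_col)[pheno_col].transform(_z)


def ordinal_recode(values, mapping: dict) -> pd.Series:
    """Collapse categorical levels onto ordinal scores (e.g. educational
    qualifications onto approximate years of schooling).

    Unmapped levels become NA; the caller decides whether to drop them.
    """
    s = pd.Series(values)
    out = s.map(mapping)
    return out


STRATIFY_MODES = ("four_group", "breastfeeding_only", "smoking_only", "eight_group_by_sex")


def stratify(
    cohort: pd.DataFrame,
    mode: str = "four_group",
    min_group: int = 50,
) -> pd.Series:
    """Assign each sample to an environment group.

    Expects columns ``breastfed`` and ``maternal_smoking`` with values in
    {'yes', 'no', 'unknown'} (anything but yes/no is treated as unknown)
    and, for ``eight_group_by_sex``, a ``sex`` column in {'M', 'F'}.
    Samples with an unknown label in any field used by the mode receive
    the label ``'excluded'``.  Groups smaller than ``min_group`` trigger a
    warning (the caller decides whether to drop them).
    """
    if mode not in STRATIFY_MODES:
        raise DomainError(f"unknown mode {mode!r}; choose from {STRATIFY_MODES}")
    for col in ("breastfed", "maternal_smoking"):
        if col not in cohort.columns:
            raise DomainError(f"cohort lacks required column {col!r}")

    bf = cohort["breastfed"].astype(str).str.lower()
    sm = cohort["maternal_smoking"].astype(str).str.lower()
    known = bf.isin(["yes", "no"]) & sm.isin(["yes", "no"])

    base = pd.Series("excluded", index=cohort.index, dtype=object)
    four = (
        np.where(bf == "yes", "B", "NB")
        + "&"
        + np.where(sm == "yes", "S", "NS")
    )
    if mode == "four_group":
        base[known] = four[known]
    elif mode == "breastfeeding_only":
        known = bf.isin(["yes", "no"])
        base[known] = np.where(bf[known] == "yes", "B", "NB")
    elif mode == "smoking_only":
        known = sm.isin(["yes", "no"])
        base[known] = np.where(sm[known] == "yes", "S", "NS")
    else:  # eight_group_by_sex
        if "sex" not in cohort.columns:
            raise DomainError("eight_group_by_sex requires a 'sex' column")
        sex = cohort["sex"].astype(str).str.upper().str[0]
        known &= sex.isin(["M", "F"])
        base[known] = pd.Series(four, index=cohort.index)[known] + "_" + sex[known]

    expected = {
        "four_group": list(FOUR_GROUPS),
        "breastfeeding_only": ["B", "NB"],
        "smoking_only": ["S", "NS"],
        "eight_group_by_sex": [f"{g}_{s}" for g in FOUR_GROUPS for s in ("M", "F")],
    }[mode]
    sizes = (
        base[base != "excluded"].value_counts().reindex(expected, fill_value=0)
    )
    small = sizes[sizes < min_group]
    if len(small):
        warnings.warn(
            f"groups below the size floor ({min_group}): {small.to_dict()}"
        )
    return base
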