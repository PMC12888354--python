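"""Mixed-type association matrices with per-pair method dispatch.

Association between two cohort variables is measured by the statistic suited
to their declared kinds: Pearson's r for two continuous variables, Cramer's V
for two categoricals, and eta-squared from one-way ANOVA for a
continuous-categorical pair.  The chi-square behind Cramer's V is computed
without Yates continuity correction — the uncorrected statistic is the
dialect that reproduces the cohort's published group-comparison p-values.

Undefined entries (too few paired observations, zero variance, degenerate
contingency margins) are stored as NaN and excluded from any downstream
edge construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CohortTable

__all__ = [
    "MissingPolicy",
    "AssociationMatrix",
    "pearson_r",
    "cramers_v",
    "eta_squared",
    "build_matrix",
    "prune_collinear",
]

CATEGORICAL_KINDS = {"binary", "nominal", "ordinal"}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation on pairwise-complete observations.

    Returns NaN (an undefined-entry sentinel) when fewer than 3 complete
    pairs remain or either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def cramers_v(table: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Cramer's V = sqrt(chi2 / (N * min(r-1, c-1))), chi2 uncorrected.

    Rows/columns with zero margin are dropped first; a table that is not at
    least 2x2 afterwards yields NaN.
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan")
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    n = t.sum()
    k = min(t.shape[0] - 1, t.shape[1] - 1)
    return float(np.sqrt(chi2 / (n * k)))


def eta_squared(x: Sequence[float], g: Sequence) -> float:
    """One-way-ANOVA effect size SS_between / SS_total.

    NaN when fewer than two groups remain or the total variance is zero.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=object)
    keep = ~np.isnan(x) & ~pd.isna(g)
    x, g = x[keep], g[keep]
    groups = pd.unique(g)
    if len(groups) < 2:
        return float("nan")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0:
        return float("nan")
    ss_between = sum(
        len(xk) * (xk.mean() - grand) ** 2 for xk in (x[g == k] for k in groups)
    )
    return float(ss_between / ss_total)


@dataclass(frozen=True)
class MissingPolicy:
    """Missing-data handling applied before association computation.

    ``continuous`` is one of ``complete_case`` (pairwise deletion, the
    default), ``listwise`` (drop any subject with a missing value anywhere)
    or ``mean_impute``.  ``binary_zero_fill`` replaces missing binary cells
    with the reference (absence) category before computation.
    """

    continuous: str = "complete_case"
    binary_zero_fill: bool = True

    def __post_init__(self) -> None:
        if self.continuous not in ("complete_case", "listwise", "mean_impute"):
            raise ValueError(f"unknown continuous policy {self.continuous!r}")


@dataclass
class AssociationMatrix:
    """Symmetric mixed-type association matrix with per-entry provenance.

    ``values`` holds the association (signed for Pearson, in [0, 1] for
    Cramer's V and eta-squared, NaN where undefined), ``method`` the
    statistic used per entry, and ``n_used`` the subjects contributing.
    """

    variables: tuple[str, ...]
    values: pd.DataFrame
    method: pd.DataFrame
    n_used: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("association matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")

    @property
    def p(self) -> int:
        return len(self.variables)

    def subset(self, variables: Sequence[str]) -> "AssociationMatrix":
        v = list(variables)
        return AssociationMatrix(
            tuple(v),
            self.values.loc[v, v],
            self.method.loc[v, v],
            self.n_used.loc[v, v],
            {k: self.kinds[k] for k in v if k in self.kinds},
        )

    def abs_values(self) -> pd.DataFrame:
        return self.values.abs()


def _resolve_input(cohort, kinds):
    if isinstance(cohort, CohortTable):
        return cohort.data, cohort.kinds, {s.name: s for s in cohort.specs}
    if kinds is None:
        raise ValueError("kinds mapping is required when passing a plain DataFrame")
    return cohort, dict(kinds), {}


def _method_for(kind_a: str, kind_b: str) -> str:
    a_cat = kind_a in CATEGORICAL_KINDS
    b_cat = kind_b in CATEGORICAL_KINDS
    if not a_cat and not b_cat:
        return "pearson"
    if a_cat and b_cat:
        return "cramers_v"
    return "eta_squared"


def build_matrix(
    cohort: CohortTable | pd.DataFrame,
    kinds: Mapping[str, str] | None = None,
    policy: MissingPolicy | None = None,
    sqrt_eta: bool = False,
) -> AssociationMatrix:
    """Assemble the full pairwise association matrix of a cohort.

    The statistic per pair follows the declared variable kinds.  The missing
    data policy is applied first: binary cells may be zero-filled with the
    reference category, continuous cells are handled pairwise-complete,
    listwise, or mean-imputed.  ``sqrt_eta`` stores the correlation ratio
    (sqrt of eta-squared) instead of eta-squared for scale comparability
    with \\|r\\| and V; off by default.
    """
    df, kind_map, spec_map = _resolve_input(cohort, kinds)
    policy = policy or MissingPolicy()
    variables = list(df.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    unknown = set(variables) - set(kind_map)
    if unknown:
        raise ValueError(f"variables without declared kind: {sorted(unknown)}")
    all_missing = [v for v in variables if df[v].isna().all()]
    if all_missing:
        raise ValueError(f"variables with no observed values: {all_missing}")

    work = df.copy()
    if policy.binary_zero_fill:
        for v in variables:
            if kind_map[v] == "binary" and work[v].isna().any():
                if v in spec_map:
                    fill = spec_map[v].marginal.labels[0]
                elif pd.api.types.is_numeric_dtype(work[v]):
                    fill = 0
                else:
                    raise ValueError(
                        f"{v}: binary zero-fill needs declared categories or numeric coding"
                    )
                work[v] = work[v].fillna(fill)
    if policy.continuous == "mean_impute":
        for v in variables:
            if kind_map[v] not in CATEGORICAL_KINDS:
                work[v] = work[v].fillna(work[v].mean())
    elif policy.continuous == "listwise":
        work = work.dropna()
        if len(work) < 3:
            raise ValueError("listwise deletion leaves fewer than 3 subjects")

    p = len(variables)
    vals = np.eye(p)
    meth = np.full((p, p), "", dtype=object)
    nuse = np.zeros((p, p), dtype=int)
    for i in range(p):
        nuse[i, i] = int(work[variables[i]].notna().sum())
    for i in range(p):
        for j in range(i + 1, p):
            a, b = variables[i], variables[j]
            method = _method_for(kind_map[a], kind_map[b])
            xa, xb = work[a], work[b]
            keep = xa.notna() & xb.notna()
            n_pair = int(keep.sum())
            if method == "pearson":
                val = pearson_r(xa[keep].to_numpy(float), xb[keep].to_numpy(float))
            elif method == "cramers_v":
                val = cramers_v(pd.crosstab(xa[keep], xb[keep]).to_numpy())
            else:
                cont, cat = (a, b) if kind_map[a] not in CATEGORICAL_KINDS else (b, a)
                val = eta_squared(
                    work[cont][keep].to_numpy(float), work[cat][keep].to_numpy(object)
                )
                if sqrt_eta and not np.isnan(val):
                    val = float(np.sqrt(val))
            vals[i, j] = vals[j, i] = val
            meth[i, j] = meth[j, i] = method
            nuse[i, j] = nuse[j, i] = n_pair

    idx = pd.Index(variables)
    return AssociationMatrix(
        tuple(variables),
        pd.DataFrame(vals, index=idx, columns=idx),
        pd.DataFrame(meth, index=idx, columns=idx),
        pd.DataFrame(nuse, index=idx, columns=idx),
        {v: kind_map[v] for v in variables},
    )


def prune_collinear(
    matrix: AssociationMatrix, cutoff: float = 0.90
) -> tuple[AssociationMatrix, list[tuple[str, str]]]:
    """Greedily drop variables until no off-diagonal \\|association\\| >= cutoff.

    From each violating pair the member with the larger mean absolute
    association to all other variables is removed (ties break toward the
    later variable in declared order), so one of a redundant pair always
    survives.  Returns the pruned matrix and a list of
    (removed_variable, triggering_partner).
    """
    removed: list[tuple[str, str]] = []
    current = matrix
    while True:
        vals = current.abs_values().to_numpy()
        np.fill_diagonal(vals, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mask = np.nan_to_num(vals) >= cutoff
        if not mask.any():
            return current, removed
        i, j = np.argwhere(mask)[0]
        mean_abs = np.nanmean(np.where(np.eye(len(vals), dtype=bool), np.nan, vals), axis=1)
        # drop the more redundant member; ties -> later declared variable
        if mean_abs[i] > mean_abs[j]:
            drop, partner = i, j
        elif mean_abs[j] > mean_abs[i]:
            drop, partner = j, i
        else:
            drop, partner = max(i, j), min(i, j)
        removed.append((current.variables[drop], current.variables[partner]))
        keep = [v for k, v in enumerate(current.variables) if k != drop]
        current = current.subset(keep)
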