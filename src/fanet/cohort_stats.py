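"""Descriptive statistics, group comparisons, reliability and sample size.

Reproduces the cohort-description machinery: Kolmogorov-Smirnov normality
branching (mean +/- SD with t-tests for normal variables, median (min-max)
with Mann-Whitney otherwise), uncorrected chi-square for categorical group
comparisons, Cronbach's alpha for scale reliability, and the a priori
two-sample t-test power computation used to size the study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CohortTable

__all__ = [
    "NormalityResult",
    "normality_check",
    "group_compare",
    "cronbach_alpha",
    "sample_size_ttest",
    "ttest_power",
    "nodes_rule_min_n",
    "descriptive_table",
]


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    p: float
    statistic: float
    method: str


def normality_check(
    x: Sequence[float], alpha: float = 0.05, method: str = "ks"
) -> NormalityResult:
    """Kolmogorov-Smirnov test against a normal with the sample mean/SD.

    The plain KS test with estimated parameters is anti-conservative;
    ``method="lilliefors"`` applies the Lilliefors correction instead.
    Normal iff p > alpha.  Constant vectors are non-normal (with a
    warning); n < 4 is rejected.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant vector; treating as non-normal")
        return NormalityResult(False, 0.0, 1.0, method)
    if method == "ks":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    elif method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return NormalityResult(bool(p > alpha), float(p), float(stat), method)


def group_compare(
    x: Sequence,
    g: Sequence,
    kind: str = "continuous",
    alpha: float = 0.05,
    branch: str | None = None,
) -> tuple[str, float]:
    """Two-group comparison with automatic test selection.

    Categorical: uncorrected chi-square on the contingency table.
    Continuous: Student's t-test when both groups pass the KS normality
    check, Mann-Whitney otherwise (exact when both groups have n <= 20,
    normal approximation with tie correction otherwise).  ``branch``
    ("t_test" or "mann_whitney") overrides the automatic choice, e.g. to
    keep the test consistent with a pooled normality verdict.
    Returns (test name, two-sided p).
    """
    x = pd.Series(list(x))
    g = pd.Series(list(g))
    keep = x.notna() & g.notna()
    x, g = x[keep], g[keep]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = x[g == levels[0]]
    b = x[g == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")

    if kind != "continuous":
        table = pd.crosstab(x, g).to_numpy()
        res = stats.chi2_contingency(table, correction=False)
        return "chi_square", float(res.pvalue)

    a = a.astype(float)
    b = b.astype(float)
    if branch is None:
        both_normal = (
            len(a) >= 4
            and len(b) >= 4
            and normality_check(a, alpha).normal
            and normality_check(b, alpha).normal
        )
    elif branch in ("t_test", "mann_whitney"):
        both_normal = branch == "t_test"
    else:
        raise ValueError(f"unknown branch {branch!r}")
    if both_normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        return "t_test", float(res.pvalue)
    use_exact = len(a) <= 20 and len(b) <= 20
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    return "mann_whitney", float(res.pvalue)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Internal-consistency reliability of a subject x item score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total
    score), with sample (ddof=1) variances.
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 items")
    if np.isnan(m).any():
        raise ValueError("complete cases only; drop or impute missing items first")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    item_var = m.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def ttest_power(n_per_group: int, effect_size_d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    nc = effect_size_d * np.sqrt(n_per_group / 2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_ttest(
    effect_size_d: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Smallest total n (equal groups) reaching the target t-test power.

    Searches the per-group size upward until the exact noncentral-t power
    meets the target and returns twice that size.
    """
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    n = 2
    while ttest_power(n, effect_size_d, alpha) < power:
        n += 1
        if n > 1_000_000:
            raise RuntimeError("sample size search did not terminate")
    return 2 * n


def nodes_rule_min_n(max_network_size: int, per_node: int = 10) -> int:
    """Minimum cohort size under the participants-per-network-node rule."""
    if max_network_size < 1 or per_node < 1:
        raise ValueError("inputs must be positive")
    return max_network_size * per_node


def descriptive_table(
    cohort: CohortTable, group: str = "sex", alpha: float = 0.05
) -> pd.DataFrame:
    """Cohort description stratified by a two-level grouping variable.

    Categorical rows report n (%) per level and group; continuous rows
    report mean +/- SD or median (min-max) depending on the KS normality
    verdict, with the matching comparison test.  One row per variable (or
    per category level), mirroring the published descriptive table.
    """
    df = cohort.data
    kinds = cohort.kinds
    if group not in df.columns:
        raise KeyError(group)
    glev = [l for l in cohort.spec(group).marginal.labels]
    rows = []
    for spec in cohort.specs:
        v = spec.name
        if v == group:
            continue
        col = df[v]
        keep = col.notna() & df[group].notna()
        col, gv = col[keep], df[group][keep]
        if spec.is_categorical:
            test, p = group_compare(col, gv, kind="categorical")
            for label in spec.marginal.labels:
                cells = {}
                for lev in glev:
                    sub = col[gv == lev]
                    n = int((sub == label).sum())
                    pct = 100 * n / len(sub) if len(sub) else np.nan
                    cells[lev] = f"{n} ({pct:.1f})"
                rows.append(
                    {"variable": v, "level": label, **cells,
                     "test": test, "p": round(p, 3), "normal": ""}
                )
        else:
            verdict = normality_check(col.astype(float), alpha).normal
            test, p = group_compare(
                col, gv, kind="continuous", alpha=alpha,
                branch="t_test" if verdict else "mann_whitney",
            )
            cells = {}
            for lev in glev:
                sub = col[gv == lev].astype(float)
                if verdict:
                    cells[lev] = f"{sub.mean():.1f} ± {sub.std(ddof=1):.1f}"
                else:
                    cells[lev] = f"{sub.median():.1f} ({sub.min():.1f}–{sub.max():.1f})"
            rows.append(
                {"variable": v, "level": "", **cells,
                 "test": test, "p": round(p, 3),
                 "normal": "normal" if verdict else "non-normal"}
            )
    return pd.DataFrame(rows)
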