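"""Univariable group comparisons and correlations.

Continuous variables are compared between the metastasis and non-metastasis
groups with the Mann-Whitney U test (exact enumeration when both groups have
n <= 10 and there are no ties, otherwise the tie-corrected normal
approximation with continuity correction); 2x2 categorical tables use the
Fisher exact test (two-sided by the probability-mass rule) and larger tables
the Pearson chi-squared test.  Correlations are Spearman rank correlations on
midranks.  All p-values are two-sided.  Missing values are dropped
complete-case per comparison and the exclusion count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "GroupComparison",
    "mann_whitney",
    "fisher_exact_2x2",
    "chi_squared",
    "spearman",
    "compare_groups",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


def mann_whitney(group_a, group_b) -> Tuple[float, float]:
    """Mann-Whitney U (of ``group_a``) and two-sided p.

    Exact p by enumeration of the U null distribution when both samples have
    n <= 10 and the pooled data carry no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by the probability-mass rule: the sum of hypergeometric
    probabilities of all tables (at the observed margins) no more probable
    than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsError(
            f"Fisher exact test is for 2x2 tables, got shape {t.shape}; "
            "use chi_squared for larger tables"
        )
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise StatsError("table must hold nonnegative counts")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_squared(table) -> Tuple[float, int, float]:
    """Pearson chi-squared test (no continuity correction) on an r x c table.

    Returns ``(statistic, df, p)``; raises on zero row/column margins.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise StatsError("chi-squared requires an r x c table with r, c >= 2")
    if np.any(t < 0):
        raise StatsError("table must hold nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError("zero row or column margin; drop empty categories first")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def spearman(x, y) -> Tuple[float, float]:
    """Spearman rank correlation (midranks) and its t-approximation p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise StatsError("spearman requires equal-length samples of size >= 3")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise StatsError("correlation undefined for a constant vector")
    res = sps.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """One row of a group-comparison table.

    For continuous variables ``group_stats`` maps group label -> dict with
    n/mean/sd/min/max; for categorical variables ``table`` holds the
    category x group contingency counts.
    """

    variable: str
    kind: str  # "continuous" | "categorical"
    test: str
    statistic: Optional[float]
    p_value: float
    n_excluded_missing: int
    group_stats: Optional[Dict[int, Dict[str, float]]] = None
    table: Optional[pd.DataFrame] = None
    df: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "kind": self.kind,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_excluded_missing": self.n_excluded_missing,
        }
        if self.group_stats is not None:
            d["group_stats"] = {str(k): v for k, v in self.group_stats.items()}
        if self.table is not None:
            d["table"] = {
                str(cat): {str(g): int(v) for g, v in row.items()}
                for cat, row in self.table.to_dict(orient="index").items()
            }
        if self.df is not None:
            d["df"] = self.df
        return d


def compare_groups(
    cohort: pd.DataFrame, variable: str, kind: str, group_col: str = "group"
) -> GroupComparison:
    """Compare one variable between the two outcome groups.

    ``kind="continuous"`` gives Mann-Whitney plus per-group mean, SD and
    range; ``kind="categorical"`` builds the category x group table and runs
    Fisher (2x2) or chi-squared (larger).  Rows with a missing value of the
    variable are excluded and counted.
    """
    if variable not in cohort.columns:
        raise StatsError(f"unknown variable {variable!r}")
    if kind not in ("continuous", "categorical"):
        raise StatsError(f"kind must be 'continuous' or 'categorical', got {kind!r}")
    col = cohort[variable]
    if kind == "categorical":
        missing = col.isna() | (col.astype(str).str.strip() == "")
    else:
        missing = pd.to_numeric(col, errors="coerce").isna()
    data = cohort.loc[~missing]
    n_excl = int(missing.sum())
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise StatsError(
            f"need exactly two groups in {group_col!r}, found {groups}"
        )

    if kind == "continuous":
        vals = {g: data.loc[data[group_col] == g, variable].astype(float) for g in groups}
        u, p = mann_whitney(vals[groups[0]], vals[groups[1]])
        stats_d = {
            int(g): {
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "min": float(v.min()),
                "max": float(v.max()),
            }
            for g, v in vals.items()
        }
        return GroupComparison(
            variable=variable,
            kind=kind,
            test="mann-whitney",
            statistic=u,
            p_value=p,
            n_excluded_missing=n_excl,
            group_stats=stats_d,
        )

    table = pd.crosstab(data[variable], data[group_col])
    table = table.loc[table.sum(axis=1) > 0, :]
    if table.shape == (2, 2):
        p = fisher_exact_2x2(table.to_numpy())
        return GroupComparison(
            variable=variable,
            kind=kind,
            test="fisher-exact",
            statistic=None,
            p_value=p,
            n_excluded_missing=n_excl,
            table=table,
        )
    stat, dof, p = chi_squared(table.to_numpy())
    return GroupComparison(
        variable=variable,
        kind=kind,
        test="chi-squared",
        statistic=stat,
        p_value=p,
        n_excluded_missing=n_excl,
        table=table,
        df=dof,
    )
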