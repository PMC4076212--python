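"""Descriptive summaries: prevalence cross-tabs, association tests, crude ORs.

Mirrors the usual DHS-report layout: per-stratum counts of overweight/obese
vs normal weight with row-wise percentages (share overweight within the
stratum), a chi-square test per categorical table, Mann-Whitney U for
continuous covariates, and crude (unadjusted) odds ratios from 2x2 counts.
All summaries are unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AnalysisSet

__all__ = [
    "CrossTab",
    "crude_prevalence",
    "chi_square_test",
    "mann_whitney_u",
    "crude_odds_ratio",
    "cross_tabulate",
    "describe",
]


@dataclass
class CrossTab:
    variable: str
    table: pd.DataFrame  # index = levels; columns n_case, n_control, percent_case
    statistic: float
    df: int
    p_value: float
    test: str


def crude_prevalence(n1: int, n0: int) -> float:
    """Percent overweight/obese in a stratum, 100*n1/(n1+n0), to 1 decimal."""
    if n1 + n0 <= 0:
        raise ValueError("empty stratum: prevalence undefined")
    return round(100.0 * n1 / (n1 + n0), 1)


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square for an r x 2 count table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D count table")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("zero row or column marginal: expected counts undefined")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    Returns ``(U, p)`` where U is the smaller of the two U statistics. Exact
    enumeration when min(n) <= 8 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = min(float(res.statistic), float(x.size * y.size - res.statistic))
    return u, float(res.pvalue)


def crude_odds_ratio(
    a: int, b: int, c: int, d: int, level: float = 0.95, continuity: bool = False
) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio ad/(bc) with a Woolf (log-scale Wald) CI.

    Layout: ``a``/``b`` cases/controls in the exposed row, ``c``/``d`` in the
    reference row. Zero cells raise by default; ``continuity=True`` adds 0.5
    to every cell instead.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(cells == 0):
        if not continuity:
            raise ValueError("zero cell; pass continuity=True for the 0.5 correction")
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt((1.0 / cells).sum())
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), (float(lo), float(hi))


def cross_tabulate(analysis: AnalysisSet, variable: str) -> CrossTab:
    """Counts of y=1 / y=0 per level of ``variable`` with a chi-square test."""
    df = analysis.data
    counts = (
        df.groupby(variable, observed=False)["y"]
        .agg(n_case="sum", n_total="count")
        .assign(n_control=lambda t: t["n_total"] - t["n_case"])
        .drop(columns="n_total")
    )
    counts = counts.loc[counts.sum(axis=1) > 0]
    counts["percent_case"] = [
        crude_prevalence(r.n_case, r.n_control) for r in counts.itertuples()
    ]
    stat, dof, p = chi_square_test(counts[["n_case", "n_control"]].to_numpy())
    return CrossTab(variable, counts, stat, dof, p, "chi-square")


def describe(
    analysis: AnalysisSet,
    categorical: tuple[str, ...] = ("state", "wealth", "educ_respondent",
                                   "educ_partner", "residence", "religion", "ethnicity"),
    continuous: tuple[str, ...] = ("age_respondent", "age_partner"),
) -> dict[str, object]:
    """Table-style summary: cross-tabs per categorical variable, mean (SD) and
    Mann-Whitney comparison per continuous variable, plus marginal shares."""
    out: dict[str, object] = {"crosstabs": {}, "continuous": {}, "marginals": {}}
    df = analysis.data
    for var in categorical:
        if var in df.columns:
            ct = cross_tabulate(analysis, var)
            out["crosstabs"][var] = ct
            out["marginals"][var] = (
                df[var].value_counts(normalize=True, sort=False) * 100
            ).round(1)
    for var in continuous:
        if var not in df.columns:
            continue
        x = df.loc[df["y"] == 1, var].dropna().to_numpy()
        y = df.loc[df["y"] == 0, var].dropna().to_numpy()
        u, p = mann_whitney_u(x, y)
        out["continuous"][var] = {
            "mean_case": float(np.mean(x)), "sd_case": float(np.std(x, ddof=1)),
            "mean_control": float(np.mean(y)), "sd_control": float(np.std(y, ddof=1)),
            "U": u, "p_value": p,
        }
    return out


def crosstab_frame(summary: dict[str, object]) -> pd.DataFrame:
    """Flatten the cross-tabs of :func:`describe` into one tidy frame."""
    rows = []
    for var, ct in summary["crosstabs"].items():
        for level, r in ct.table.iterrows():
            rows.append({
                "variable": var, "level": level,
                "n_case": int(r.n_case), "n_control": int(r.n_control),
                "percent_case": r.percent_case,
                "chi2": ct.statistic, "df": ct.df, "p_value": ct.p_value,
            })
    return pd.DataFrame(rows)
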