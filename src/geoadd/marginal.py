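"""Maximum-likelihood logistic regression for marginal adjusted odds ratios.

Age enters grouped here (respondent <=25 / 26-35 / 36-49, partner <=30 /
31-40 / 41+), matching the conventional table presentation; the geo-additive
model treats age continuously instead. Confidence intervals are Wald on the
log-odds scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core_io import Codebook, default_codebook
from .preprocess import AnalysisSet

__all__ = [
    "DesignMatrix",
    "FitResult",
    "DesignError",
    "SeparationWarning",
    "build_design",
    "fit_logistic_irls",
    "or_table",
]

AGE_GROUPS_RESPONDENT = ((15, 25, "<=25"), (26, 35, "26-35"), (36, 49, "36-49"))
AGE_GROUPS_PARTNER = ((15, 30, "<=30"), (31, 40, "31-40"), (41, 200, "41+"))


class DesignError(ValueError):
    pass


class SeparationWarning(UserWarning):
    pass


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]  # parallel to X columns; "(Intercept)" first
    reference_rows: list[str]  # labels for reference levels (printed as 1.00)


@dataclass
class FitResult:
    coef: np.ndarray
    cov: np.ndarray
    columns: list[str]
    converged: bool
    iterations: int
    log_likelihood: float
    deviance_path: list[float]


def _age_group(values: np.ndarray, groups) -> pd.Categorical:
    labels = [g[2] for g in groups]
    bins = [groups[0][0] - 0.5] + [g[1] + 0.5 for g in groups]
    return pd.cut(values, bins=bins, labels=labels)


def build_design(
    analysis: AnalysisSet,
    codebook: Codebook | None = None,
    covariates: tuple[str, ...] = ("educ_respondent", "educ_partner", "residence",
                                   "religion", "wealth", "ethnicity", "state"),
    include_age_groups: bool = True,
) -> DesignMatrix:
    """Dummy-coded design with intercept; reference level of each covariate
    (first codebook level) is omitted."""
    codebook = codebook or default_codebook()
    df = analysis.data
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["(Intercept)"]
    refs: list[str] = []

    def add_categorical(name: str, values: pd.Categorical, levels) -> None:
        refs.append(f"{name}[{levels[0]}]")
        for lv in levels[1:]:
            if (values == lv).sum() == 0:
                continue  # unobserved level: no estimable column
            cols.append((values == lv).to_numpy(dtype=float))
            names.append(f"{name}[{lv}]")

    if include_age_groups:
        ag = _age_group(df["age_respondent"].to_numpy(), AGE_GROUPS_RESPONDENT)
        add_categorical("age_respondent", pd.Series(ag), [g[2] for g in AGE_GROUPS_RESPONDENT])
        if "age_partner" in df.columns:
            pg = _age_group(df["age_partner"].to_numpy(), AGE_GROUPS_PARTNER)
            add_categorical("age_partner", pd.Series(pg), [g[2] for g in AGE_GROUPS_PARTNER])
    for var in covariates:
        if var in df.columns:
            levels = [lv for lv in codebook.levels(var)]
            add_categorical(var, df[var], levels)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if abs(r[i, i]) < tol]
        raise DesignError(f"rank-deficient design; collinear column(s): {bad}")
    return DesignMatrix(X, names, refs)


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    return -2.0 * float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))


def fit_logistic_irls(
    design: DesignMatrix | np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Logistic regression by iteratively reweighted least squares.

    Converges when the deviance changes by less than ``tol``; step-halving
    keeps the deviance non-increasing. Quasi-complete separation is flagged
    (|coef| > 15 while the deviance is still falling) with a warning.
    """
    if isinstance(design, DesignMatrix):
        X, names = design.X, design.columns
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")

    beta = np.zeros(X.shape[1])
    mu = np.full(y.shape, y.mean() if 0 < y.mean() < 1 else 0.5)
    dev = _deviance(y, mu)
    path = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        # Newton step via weighted least squares
        xtw = X.T * w
        step = linalg.solve(xtw @ X, X.T @ (y - mu), assume_a="pos")
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            dev_new = _deviance(y, 1.0 / (1.0 + np.exp(-(X @ cand))))
            if dev_new <= dev + 1e-10:
                break
            factor /= 2.0
        beta = beta + factor * step
        dev_new = _deviance(y, 1.0 / (1.0 + np.exp(-(X @ beta))))
        path.append(dev_new)
        if abs(dev - dev_new) < tol:
            converged = True
            dev = dev_new
            break
        dev = dev_new
    if not converged:
        warnings.warn(f"IRLS did not converge in {it} iterations", stacklevel=2)
    if np.any(np.abs(beta) > 15.0):
        warnings.warn(
            "possible (quasi-)complete separation: |coefficient| > 15",
            SeparationWarning, stacklevel=2,
        )
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = linalg.inv((X.T * w) @ X)
    ll = -dev / 2.0
    return FitResult(beta, cov, names, converged, it, ll, path)


def or_table(fit: FitResult, level: float = 0.95,
             reference_rows: list[str] | None = None) -> pd.DataFrame:
    """Odds ratios exp(coef) with Wald CIs; reference rows print as 1.00."""
    if not fit.converged:
        raise RuntimeError("refusing to summarize a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.diag(fit.cov))
    rows = []
    for name, b, s in zip(fit.columns, fit.coef, se):
        if name == "(Intercept)":
            continue
        with np.errstate(over="ignore"):  # separated levels may have inf bounds
            rows.append({
                "term": name, "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)), "ci_high": float(np.exp(b + z * s)),
                "log_odds": float(b), "se": float(s), "reference": False,
            })
    for name in reference_rows or []:
        rows.append({"term": name, "odds_ratio": 1.0, "ci_low": np.nan,
                     "ci_high": np.nan, "log_odds": 0.0, "se": np.nan,
                     "reference": True})
    return pd.DataFrame(rows)
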