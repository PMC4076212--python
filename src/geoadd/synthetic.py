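"""DHS-like synthetic survey generator with known ground truth.

Generates individual records on a region graph whose binary outcome
(overweight/obese vs normal weight) follows a logit model with configurable
fixed effects, smooth age effects, ICAR-distributed structured spatial
effects and iid unstructured region effects, plus an underweight stratum to
exercise downstream exclusion. BMI values are drawn uniformly inside the
destination WHO band so that categorization is exactly invertible.

Default marginal covariate distributions and effect sizes mimic the published
NDHS-2008 profile of Nigerian women aged 15-49 (education, religion, wealth,
ethnicity shares; urban fraction 26.6%; underweight fraction 12%; overall
overweight/obesity prevalence near 20.9%); the default smooth age effects
peak near 45 years for respondents and near 70 for partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core_io import RegionGraph, default_codebook

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "make_lattice_graph",
    "draw_icar_effects",
    "simulate_survey",
    "default_f_age",
    "default_f_page",
    "DEFAULT_CATEGORY_PROBS",
    "DEFAULT_BETA",
]

# Marginal covariate distributions (NDHS-2008-like shares).
DEFAULT_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "educ_respondent": {"none": 0.503, "primary": 0.229, "secondary": 0.221, "higher": 0.047},
    "educ_partner": {"none": 0.414, "primary": 0.214, "secondary": 0.264, "higher": 0.108},
    "residence": {"rural": 0.734, "urban": 0.266},
    "religion": {"catholic": 0.086, "other_christian": 0.326, "islam": 0.567,
                 "traditionalist": 0.019, "other": 0.001},
    "wealth": {"poorest": 0.265, "poorer": 0.240, "middle": 0.196,
               "richer": 0.166, "richest": 0.133},
    "ethnicity": {"ekoi": 0.015, "fulani": 0.096, "hausa": 0.282, "ibibio": 0.016,
                  "igala": 0.012, "igbo": 0.105, "ijaw_izon": 0.031,
                  "kanuri_beriberi": 0.033, "tiv": 0.028, "yoruba": 0.108,
                  "others": 0.275},
}

# Log-odds effects per non-reference covariate level (NDHS-2008-like odds
# ratios on the covariates the analysis adjusts for).
DEFAULT_BETA: dict[str, float] = {
    "educ_respondent[primary]": math.log(1.17),
    "educ_respondent[secondary]": math.log(1.49),
    "educ_respondent[higher]": math.log(1.68),
    "educ_partner[primary]": math.log(0.83),
    "educ_partner[secondary]": math.log(0.81),
    "educ_partner[higher]": math.log(0.96),
    "residence[urban]": math.log(1.24),
    "religion[other_christian]": math.log(0.77),
    "religion[islam]": math.log(0.74),
    "religion[traditionalist]": math.log(0.75),
    "religion[other]": math.log(1.49),
    "wealth[poorer]": math.log(1.19),
    "wealth[middle]": math.log(1.89),
    "wealth[richer]": math.log(2.44),
    "wealth[richest]": math.log(3.45),
}


def default_f_age(age) -> np.ndarray:
    """Smooth respondent-age effect, maximum near 45 on [15, 49]."""
    return 0.9 * np.sin(np.pi * (np.asarray(age, dtype=float) - 15.0) / 60.0)


def default_f_page(age) -> np.ndarray:
    """Smooth partner-age effect, maximum near 70 on [15, 95]."""
    return 0.5 * np.sin(np.pi * (np.asarray(age, dtype=float) - 15.0) / 110.0)


@dataclass
class SimulationConfig:
    n_individuals: int = 5000
    graph: RegionGraph | None = None  # default: 6x6 lattice
    intercept: float | None = None  # None: calibrated to ~20.9% prevalence
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    f_age: Callable = default_f_age
    f_page: Callable = default_f_page
    tau2_spat: float = 0.5
    tau2_unstr: float = 0.05
    p_underweight: float = 0.12
    p_missing_partner: float = 0.0
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_PROBS.items()}
    )
    region_weights: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2_spat < 0 or self.tau2_unstr < 0:
            raise ValueError("variances must be nonnegative")
        if not 0.0 <= self.p_underweight <= 1.0:
            raise ValueError("p_underweight must be in [0, 1]")
        for var, probs in self.category_probs.items():
            p = np.array(list(probs.values()), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=5e-3):
                raise ValueError(f"probabilities for {var!r} must be >= 0 and sum to 1")


@dataclass
class SimulatedTruth:
    """Ground truth behind one simulated survey."""

    spatial_effects: pd.Series  # structured (ICAR), per region
    unstructured_effects: pd.Series
    beta: dict[str, float]
    intercept: float
    age_grid: np.ndarray
    f_age_grid: np.ndarray  # centered to mean zero over the grid
    page_grid: np.ndarray
    f_page_grid: np.ndarray
    latent_y: np.ndarray  # per-record outcome (-1 for underweight stratum)
    eta: np.ndarray


def make_lattice_graph(m: int) -> RegionGraph:
    """m x m rook-adjacency lattice with regions labelled ``cell{i}x{j}``."""
    if m < 2:
        raise ValueError("lattice side must be at least 2")
    regions = [f"cell{i}x{j}" for i in range(m) for j in range(m)]
    edges = []
    for i in range(m):
        for j in range(m):
            if i + 1 < m:
                edges.append((f"cell{i}x{j}", f"cell{i + 1}x{j}"))
            if j + 1 < m:
                edges.append((f"cell{i}x{j}", f"cell{i}x{j + 1}"))
    return RegionGraph.from_edges(regions, edges)


def draw_icar_effects(
    graph: RegionGraph, tau2: float, seed: int | np.random.Generator, size: int = 1
) -> pd.Series | np.ndarray:
    """Draw from the intrinsic GMRF with precision Q / tau2.

    Q = degree - adjacency; draws live in the row space of Q, i.e. they sum
    to zero within each connected component, and have covariance tau2 * Q^+
    (Moore-Penrose pseudo-inverse). Returns a per-region Series for
    ``size=1``, else a (size, R) array.
    """
    if graph.n_regions == 0:
        raise ValueError("empty graph")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.diag(graph.degree().astype(float)) - graph.adjacency_matrix()
    lam, vec = np.linalg.eigh(q)
    tol = lam.max() * q.shape[0] * np.finfo(float).eps
    pos = lam > max(tol, 1e-12)
    coefs = rng.standard_normal((size, int(pos.sum()))) * np.sqrt(tau2 / lam[pos])
    effects = coefs @ vec[:, pos].T
    if size == 1:
        return pd.Series(effects[0], index=list(graph.regions))
    return effects


def _centered(f: Callable, grid: np.ndarray) -> tuple[np.ndarray, float]:
    vals = np.asarray(f(grid), dtype=float)
    c = float(vals.mean())
    return vals - c, c


def _truncated_normal_ints(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draw = np.rint(rng.normal(mean, sd, size=todo.size)).astype(int)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_survey(config: SimulationConfig) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Generate one survey and its ground truth; deterministic given the seed.

    Per individual: covariates are drawn from the configured marginals and the
    region uniformly (or by ``region_weights``); the linear predictor is
    eta = intercept + beta'x + f_age(age) + f_page(partner age) + u_s + v_s
    with f centered over their integer age grids and u/v the structured /
    unstructured region effects. With probability ``p_underweight`` the woman
    is assigned BMI ~ U[15, 18.5); otherwise y ~ Bernoulli(expit(eta)) and
    BMI ~ U[25, 35) if y = 1, else U[18.5, 25).
    """
    rng = np.random.default_rng(config.seed)
    graph = config.graph or make_lattice_graph(6)
    codebook = default_codebook(tuple(graph.regions))
    n = config.n_individuals

    age = _truncated_normal_ints(rng, n, 29.3, 7.1, 15, 49)
    page = _truncated_normal_ints(rng, n, 40.9, 12.8, 15, 95)

    cats: dict[str, np.ndarray] = {}
    for var, probs in config.category_probs.items():
        levels = np.array(list(probs.keys()))
        p = np.array(list(probs.values()), dtype=float)
        p = p / p.sum()
        cats[var] = levels[rng.choice(levels.size, size=n, p=p)]

    regions = np.asarray(graph.regions)
    if config.region_weights is not None:
        w = np.array([config.region_weights.get(r, 0.0) for r in regions])
        w = w / w.sum()
    else:
        w = np.full(regions.size, 1.0 / regions.size)
    state = regions[rng.choice(regions.size, size=n, p=w)]

    u = (draw_icar_effects(graph, config.tau2_spat, rng)
         if config.tau2_spat > 0 else pd.Series(0.0, index=list(regions)))
    v = pd.Series(
        rng.standard_normal(regions.size) * np.sqrt(config.tau2_unstr)
        if config.tau2_unstr > 0 else np.zeros(regions.size),
        index=list(regions),
    )

    age_grid = np.arange(15, 50)
    page_grid = np.arange(15, 96)
    f_age_grid, c_age = _centered(config.f_age, age_grid)
    f_page_grid, c_page = _centered(config.f_page, page_grid)

    fixed = np.zeros(n)
    for var in cats:
        for term, b in config.beta.items():
            if term.startswith(f"{var}["):
                level = term[len(var) + 1:-1]
                fixed += b * (cats[var] == level)

    if config.intercept is None:
        # calibrate so the marginal outcome probability is near 20.9%
        mean_fixed = 0.0
        for var, probs in config.category_probs.items():
            for level, p in probs.items():
                mean_fixed += config.beta.get(f"{var}[{level}]", 0.0) * p
        intercept = math.log(0.209 / 0.791) - mean_fixed
    else:
        intercept = config.intercept

    region_effect = (u + v).reindex(state).to_numpy()
    eta = (
        intercept + fixed
        + np.asarray(config.f_age(age)) - c_age
        + np.asarray(config.f_page(page)) - c_page
        + region_effect
    )

    underweight = rng.random(n) < config.p_underweight
    y = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-eta)), 1, 0)
    y = np.where(underweight, -1, y)
    bmi = np.where(
        underweight,
        rng.uniform(15.0, 18.5, size=n),
        np.where(y == 1, rng.uniform(25.0, 35.0, size=n), rng.uniform(18.5, 25.0, size=n)),
    )

    records = pd.DataFrame({
        "id": [f"w{i:07d}" for i in range(n)],
        "age_respondent": age,
        "age_partner": page.astype(float),
        "bmi": np.round(bmi, 4),
        "educ_respondent": cats["educ_respondent"],
        "educ_partner": cats["educ_partner"],
        "residence": cats["residence"],
        "religion": cats["religion"],
        "wealth": cats["wealth"],
        "ethnicity": cats["ethnicity"],
        "state": state,
    })
    if config.p_missing_partner > 0:
        miss = rng.random(n) < config.p_missing_partner
        records.loc[miss, ["age_partner", "educ_partner"]] = np.nan
    for var in ("educ_respondent", "educ_partner", "residence", "religion",
                "wealth", "ethnicity", "state"):
        records[var] = pd.Categorical(records[var], categories=codebook.levels(var))

    truth = SimulatedTruth(
        spatial_effects=u, unstructured_effects=v, beta=dict(config.beta),
        intercept=intercept, age_grid=age_grid, f_age_grid=f_age_grid,
        page_grid=page_grid, f_page_grid=f_page_grid, latent_y=y, eta=eta,
    )
    return records, truth
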