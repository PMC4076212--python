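"""Posterior summaries: POR tables, nonlinear-effect curves, spatial maps.

Point summaries are posterior odds ratios POR = exp(posterior mean of the
log-odds effect) with equal-tailed quantile credible regions (CRs),
exponentiated to the odds scale. Spatial maps categorize each region's total
effect u + v by the sign rule: "positive" if the lower CR bound is above
zero, "negative" if the upper bound is below zero, "none" otherwise; the
default nominal level for maps is 80%.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .geoadditive import PosteriorDraws, spline_basis_at

__all__ = [
    "summarize_fixed",
    "nonlinear_curve",
    "categorize_map",
    "export_map",
    "format_or",
]

MAP_CATEGORIES = ("negative", "none", "positive")


def format_or(or_: float, lo: float, hi: float) -> str:
    """Render an OR with its interval in report style, e.g. ``1.24 (1.14, 1.36)``."""
    return f"{or_:.2f} ({lo:.2f}, {hi:.2f})"


def _check_draws(draws: PosteriorDraws) -> None:
    if draws.n_saved == 0:
        raise ValueError("empty posterior draws")
    if draws.n_saved < 100:
        warnings.warn(
            f"only {draws.n_saved} saved draws; quantile CRs may be unstable",
            stacklevel=3,
        )


def summarize_fixed(
    draws: PosteriorDraws, level: float = 0.95, mean_of_exp: bool = False
) -> pd.DataFrame:
    """POR table for the fixed effects with equal-tailed CRs.

    ``mean_of_exp=True`` reports E[exp(effect)] instead of exp(E[effect]) as
    the point summary. Reference levels are appended as 1.00 rows.
    """
    _check_draws(draws)
    alpha = (1.0 - level) / 2.0
    rows = []
    for j, label in enumerate(draws.beta_labels):
        if label == "(Intercept)":
            continue
        d = draws.beta[:, j]
        lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
        por = float(np.mean(np.exp(d)) if mean_of_exp else np.exp(d.mean()))
        rows.append({
            "term": label, "por": por,
            "cr_low": float(np.exp(lo)), "cr_high": float(np.exp(hi)),
            "prob_positive": float((d > 0).mean()),
            "display": format_or(por, np.exp(lo), np.exp(hi)),
            "reference": False,
        })
    for label in draws.reference_rows:
        rows.append({"term": label, "por": 1.0, "cr_low": np.nan, "cr_high": np.nan,
                     "prob_positive": np.nan, "display": "1.00", "reference": True})
    return pd.DataFrame(rows)


def nonlinear_curve(
    draws: PosteriorDraws, variable: str, grid: np.ndarray | None = None,
    level: float = 0.80,
) -> pd.DataFrame:
    """Pointwise posterior mean and equal-tailed band of a centered smooth."""
    _check_draws(draws)
    block = draws.spline_blocks[variable]
    if grid is None:
        grid = np.linspace(block.xmin, block.xmax, 101)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < block.xmin - 1e-9 or grid.max() > block.xmax + 1e-9:
        raise ValueError(
            f"grid outside the observed range [{block.xmin}, {block.xmax}] "
            f"of {variable!r}: refusing to extrapolate"
        )
    basis = spline_basis_at(grid, block.knots, block.degree)
    curves = draws.spline_coefs[variable] @ basis.T  # S x G
    curves = curves - curves.mean(axis=1, keepdims=True)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(curves, [alpha, 1.0 - alpha], axis=0)
    return pd.DataFrame({
        variable: grid,
        "posterior_mean": curves.mean(axis=0),
        "cr_low": lo,
        "cr_high": hi,
    })


def categorize_map(
    draws: PosteriorDraws, level: float = 0.80,
    observed_regions: set[str] | None = None,
) -> pd.DataFrame:
    """Sign-categorized total spatial effects u + v per region.

    Returns per region the POR (exp of posterior mean), the CR at ``level``,
    the posterior probability of a positive effect, and the category
    (positive / negative / none by whether the CR excludes zero). Regions
    absent from ``observed_regions`` (when given) are flagged: their draws
    are prior-dominated.
    """
    _check_draws(draws)
    total = draws.total_spatial()  # S x R
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(total, [alpha, 1.0 - alpha], axis=0)
    mean = total.mean(axis=0)
    category = np.where(lo > 0, "positive", np.where(hi < 0, "negative", "none"))
    out = pd.DataFrame({
        "region": list(draws.regions),
        "por": np.exp(mean),
        "cr_low": np.exp(lo),
        "cr_high": np.exp(hi),
        "prob_positive": (total > 0).mean(axis=0),
        "category": category,
    })
    out["display"] = [format_or(r.por, r.cr_low, r.cr_high) for r in out.itertuples()]
    if observed_regions is not None:
        out["prior_dominated"] = [r not in observed_regions for r in out["region"]]
        if out["prior_dominated"].any():
            warnings.warn(
                "regions without observations in map: "
                + ", ".join(out.loc[out["prior_dominated"], "region"]),
                stacklevel=2,
            )
    return out


_POR_COLORS = {  # red = elevated odds, green = reduced odds
    "high": "#b2182b", "mid": "#f7f7f7", "low": "#1a9850",
}
_CATEGORY_COLORS = {"positive": "#000000", "none": "#808080", "negative": "#ffffff"}


def export_map(
    map_table: pd.DataFrame, polygons: dict | str | Path,
    out_path: str | Path | None = None, image_path: str | Path | None = None,
) -> dict:
    """Annotate region polygons (GeoJSON) with POR, CR and category.

    Every feature must carry a region id in ``properties.region`` (or
    ``properties.id``); features gain ``por``, ``cr_low``, ``cr_high``,
    ``category`` and fill colors. Mismatched ids are reported per region.
    """
    if not isinstance(polygons, dict):
        polygons = json.loads(Path(polygons).read_text())
    by_region = map_table.set_index("region")
    feature_ids = []
    for feat in polygons.get("features", []):
        props = feat.setdefault("properties", {})
        rid = props.get("region", props.get("id"))
        feature_ids.append(rid)
    missing_polygons = sorted(set(by_region.index) - set(feature_ids))
    unknown_features = sorted(set(feature_ids) - set(by_region.index))
    if missing_polygons or unknown_features:
        raise ValueError(
            f"region/polygon id mismatch; regions without polygons: "
            f"{missing_polygons}; polygons without regions: {unknown_features}"
        )
    log_por = np.log(by_region["por"])
    scale = float(np.abs(log_por).max()) or 1.0
    for feat in polygons["features"]:
        props = feat["properties"]
        rid = props.get("region", props.get("id"))
        row = by_region.loc[rid]
        rel = float(np.log(row["por"]) / scale)  # -1 .. 1
        props.update({
            "por": float(row["por"]), "cr_low": float(row["cr_low"]),
            "cr_high": float(row["cr_high"]), "category": str(row["category"]),
            "por_color": _POR_COLORS["high"] if rel > 0.15
            else _POR_COLORS["low"] if rel < -0.15 else _POR_COLORS["mid"],
            "category_color": _CATEGORY_COLORS[str(row["category"])],
        })
    if out_path is not None:
        Path(out_path).write_text(json.dumps(polygons, indent=1))
    if image_path is not None:
        _render_map(polygons, image_path)
    return polygons


def _render_map(geojson: dict, image_path: str | Path) -> None:  # pragma: no cover
    """Best-effort choropleth rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(12, 6))
    for ax, key, title in zip(
        axes, ("por_color", "category_color"),
        ("Posterior odds ratio", "Sign category"),
    ):
        for feat in geojson["features"]:
            geom = feat["geometry"]
            rings = (geom["coordinates"] if geom["type"] == "Polygon"
                     else [r for poly in geom["coordinates"] for r in poly])
            for ring in rings:
                xy = np.asarray(ring)
                ax.fill(xy[:, 0], xy[:, 1], color=feat["properties"][key],
                        edgecolor="black", linewidth=0.5)
        ax.set_title(title)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.savefig(image_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
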