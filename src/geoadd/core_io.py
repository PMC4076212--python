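"""Data model, readers/writers and validation shared by all pipeline stages.

Individual survey records are held in a :class:`pandas.DataFrame` validated
against a :class:`Codebook`; the spatial index (state of residence) lives in a
:class:`RegionGraph` built from a plain-text neighbour list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Codebook",
    "RegionGraph",
    "SchemaError",
    "CodebookError",
    "GraphError",
    "default_codebook",
    "read_records",
    "write_records",
    "read_adjacency",
    "write_adjacency",
    "nigeria_graph",
    "NIGERIA_REGIONS",
    "MERGED_PAIRS",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the header does not match the schema."""


class CodebookError(ValueError):
    """A categorical value is not in the codebook for its variable."""


class GraphError(ValueError):
    """Adjacency input references undeclared regions or is otherwise invalid."""


# Mandatory columns of the individual-record CSV schema. ``bmi`` may be
# replaced by a (weight_kg, height_m) pair, in which case BMI is computed.
MANDATORY_COLUMNS = (
    "id",
    "age_respondent",
    "educ_respondent",
    "residence",
    "religion",
    "wealth",
    "ethnicity",
    "state",
)
OPTIONAL_COLUMNS = ("age_partner", "educ_partner", "bmi", "weight_kg", "height_m")

#: Values interpreted as missing in the CSV dialect.
NA_VALUES = (".", "")

# The 31 analysis regions: Nigeria's pre-1996 30 states plus Abuja (FCT),
# with post-1996 state splits re-merged. Reference region (lowest crude
# prevalence) listed first.
MERGED_PAIRS = {
    "Bauchi": "Bauchi/Gombe",
    "Gombe": "Bauchi/Gombe",
    "Ondo": "Ondo/Ekiti",
    "Ekiti": "Ondo/Ekiti",
    "Nassarawa": "Nassarawa/Plateau",
    "Plateau": "Nassarawa/Plateau",
    "Rivers": "Rivers/Bayelsa",
    "Bayelsa": "Rivers/Bayelsa",
    "Sokoto": "Sokoto/Zamfara",
    "Zamfara": "Sokoto/Zamfara",
    "Enugu": "Enugu/Ebonyi",
    "Ebonyi": "Enugu/Ebonyi",
}

NIGERIA_REGIONS = (
    "Yobe",
    "Abia",
    "Abuja",
    "Adamawa",
    "Akwa Ibom",
    "Anambra",
    "Bauchi/Gombe",
    "Benue",
    "Borno",
    "Cross River",
    "Delta",
    "Edo",
    "Enugu/Ebonyi",
    "Imo",
    "Jigawa",
    "Kaduna",
    "Kano",
    "Katsina",
    "Kebbi",
    "Kogi",
    "Kwara",
    "Lagos",
    "Nassarawa/Plateau",
    "Niger",
    "Ogun",
    "Ondo/Ekiti",
    "Osun",
    "Oyo",
    "Rivers/Bayelsa",
    "Sokoto/Zamfara",
    "Taraba",
)

# Spelling variants seen in published NDHS-2008 tables.
STATE_ALIASES = {
    "Oye": "Oyo",
    "Crossriver": "Cross River",
    "Enungu/Ebonyi": "Enugu/Ebonyi",
}


@dataclass(frozen=True)
class Codebook:
    """Ordered category labels per variable, reference level first."""

    variables: dict[str, tuple[str, ...]]
    aliases: dict[str, dict[str, str]] = field(default_factory=dict)

    def levels(self, variable: str) -> tuple[str, ...]:
        return self.variables[variable]

    def reference(self, variable: str) -> str:
        return self.variables[variable][0]

    def canonical(self, variable: str, value: str) -> str:
        """Resolve aliases; raise :class:`CodebookError` for unknown labels."""
        value = self.aliases.get(variable, {}).get(value, value)
        if value not in self.variables[variable]:
            raise CodebookError(
                f"unknown label {value!r} for variable {variable!r}; "
                f"expected one of {list(self.variables[variable])}"
            )
        return value

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "variables": {k: list(v) for k, v in self.variables.items()},
            "aliases": {k: dict(v) for k, v in self.aliases.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            variables={k: tuple(v) for k, v in payload["variables"].items()},
            aliases={k: dict(v) for k, v in payload.get("aliases", {}).items()},
        )


def default_codebook(regions: tuple[str, ...] = NIGERIA_REGIONS) -> Codebook:
    """Codebook with the analysis reference levels.

    References: education "none", religion "catholic", wealth "poorest",
    ethnicity "ekoi", residence "rural", state "Yobe" (lowest crude
    overweight/obesity prevalence).
    """
    educ = ("none", "primary", "secondary", "higher")
    return Codebook(
        variables={
            "educ_respondent": educ,
            "educ_partner": educ + ("missing",),
            "residence": ("rural", "urban"),
            "religion": ("catholic", "other_christian", "islam", "traditionalist", "other"),
            "wealth": ("poorest", "poorer", "middle", "richer", "richest"),
            "ethnicity": (
                "ekoi",
                "fulani",
                "hausa",
                "ibibio",
                "igala",
                "igbo",
                "ijaw_izon",
                "kanuri_beriberi",
                "tiv",
                "yoruba",
                "others",
            ),
            "state": regions,
        },
        aliases={"state": dict(STATE_ALIASES)},
    )


@dataclass(frozen=True)
class RegionGraph:
    """Region ids with symmetric adjacency and connected components."""

    regions: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]
    components: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen = set(self.regions)
        if len(seen) != len(self.regions):
            raise GraphError("duplicate region ids")
        for r, nbrs in self.neighbors.items():
            if r in nbrs:
                raise GraphError(f"self-loop at region {r!r}")
            for s in nbrs:
                if s not in seen:
                    raise GraphError(f"neighbor {s!r} of {r!r} is not a declared region")
                if r not in self.neighbors.get(s, frozenset()):
                    raise GraphError(f"asymmetric adjacency between {r!r} and {s!r}")

    @classmethod
    def from_edges(
        cls, regions: list[str] | tuple[str, ...], edges: list[tuple[str, str]]
    ) -> "RegionGraph":
        g = nx.Graph()
        g.add_nodes_from(regions)
        g.add_edges_from(edges)
        nbrs = {r: frozenset(g.neighbors(r)) for r in regions}
        comps = tuple(frozenset(c) for c in nx.connected_components(g))
        return cls(tuple(regions), nbrs, comps)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    def degree(self) -> np.ndarray:
        return np.array([len(self.neighbors[r]) for r in self.regions])

    def adjacency_matrix(self) -> np.ndarray:
        idx = {r: i for i, r in enumerate(self.regions)}
        a = np.zeros((self.n_regions, self.n_regions))
        for r, nbrs in self.neighbors.items():
            for s in nbrs:
                a[idx[r], idx[s]] = 1.0
        return a

    def component_indices(self) -> list[np.ndarray]:
        """Region indices (into ``self.regions``) for each connected component."""
        idx = {r: i for i, r in enumerate(self.regions)}
        return [np.array(sorted(idx[r] for r in comp)) for comp in self.components]

    def merge(self, mapping: dict[str, str]) -> "RegionGraph":
        """Collapse regions according to ``mapping`` (old id -> merged id)."""
        new_of = {r: mapping.get(r, r) for r in self.regions}
        merged: list[str] = []
        for r in self.regions:
            if new_of[r] not in merged:
                merged.append(new_of[r])
        edges = {
            (new_of[r], new_of[s])
            for r, nbrs in self.neighbors.items()
            for s in nbrs
            if new_of[r] != new_of[s]
        }
        return RegionGraph.from_edges(merged, sorted(edges))


def read_records(
    path: str | Path, codebook: Codebook | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read and validate an individual-record CSV.

    Returns ``(records, report)`` where ``report`` counts parsed and dropped
    rows. Rows with unparseable mandatory numeric fields are dropped with a
    logged count; unknown categorical labels raise :class:`CodebookError`
    naming the row and value. If the ``bmi`` column is absent but
    ``weight_kg``/``height_m`` are present, BMI is computed as
    weight / height**2 for every row.

    Without an explicit ``codebook``, the Nigeria analysis codebook is used
    when the file's states all belong to it; otherwise the state levels are
    taken from the file (sorted), supporting synthetic region graphs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype=str, na_values=list(NA_VALUES), keep_default_na=False, skipinitialspace=True
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if codebook is None:
        observed = {STATE_ALIASES.get(s, s) for s in df["state"].dropna().unique()}
        if observed <= set(NIGERIA_REGIONS):
            codebook = default_codebook()
        else:
            codebook = default_codebook(tuple(sorted(observed)))
    if "bmi" not in df.columns and not {"weight_kg", "height_m"} <= set(df.columns):
        raise SchemaError("need either a 'bmi' column or both 'weight_kg' and 'height_m'")

    n_in = len(df)
    num_cols = [c for c in ("age_respondent", "age_partner", "bmi", "weight_kg", "height_m")
                if c in df.columns]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    if "bmi" not in df.columns:
        df["bmi"] = df["weight_kg"] / df["height_m"] ** 2

    # Mandatory numerics must parse; BMI must be positive.
    bad = df["age_respondent"].isna() | df["bmi"].isna() | (df["bmi"] <= 0)
    bad |= ~df["age_respondent"].between(15, 49)
    if bad.any():
        logger.warning("dropping %d row(s) with unparseable/invalid mandatory fields", bad.sum())
    df = df.loc[~bad].copy()

    for var in ("educ_respondent", "educ_partner", "residence", "religion",
                "wealth", "ethnicity", "state"):
        if var not in df.columns:
            continue
        levels = codebook.levels(var)
        out = []
        for row_i, value in df[var].items():
            if pd.isna(value):
                out.append(np.nan)
                continue
            try:
                out.append(codebook.canonical(var, value))
            except CodebookError as exc:
                raise CodebookError(f"row {row_i}: {exc}") from None
        df[var] = pd.Categorical(out, categories=levels)

    df["age_respondent"] = df["age_respondent"].astype(int)
    df = df.reset_index(drop=True)
    report = {"read": n_in, "retained": len(df), "dropped_invalid": int(n_in - len(df))}
    return df, report


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write records in the CSV dialect read by :func:`read_records`."""
    out = df.copy()
    cols = [c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, na_rep=".")


def read_adjacency(path: str | Path) -> RegionGraph:
    """Parse a plain-text neighbour list into a :class:`RegionGraph`.

    Format: first line is the region count; each following non-empty line is
    ``id n_neighbors neighbor1 neighbor2 ...`` (whitespace-separated; region
    ids containing spaces use underscores in the file, so ids themselves must
    not contain underscores). Asymmetric input is symmetrized with a warning.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    try:
        n_declared = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise GraphError("first line must be the region count") from exc
    entries = []
    for ln in lines[1:]:
        parts = ln.split()
        rid, k = parts[0].replace("_", " "), int(parts[1])
        nbrs = [p.replace("_", " ") for p in parts[2:]]
        if len(nbrs) != k:
            raise GraphError(f"region {rid!r} declares {k} neighbors but lists {len(nbrs)}")
        entries.append((rid, nbrs))
    regions = [rid for rid, _ in entries]
    if len(regions) != n_declared:
        raise GraphError(f"declared {n_declared} regions but found {len(regions)}")
    declared = set(regions)
    asym = False
    edges = set()
    listed = {rid: set(nbrs) for rid, nbrs in entries}
    for rid, nbrs in entries:
        for s in nbrs:
            if s not in declared:
                raise GraphError(f"neighbor {s!r} of {rid!r} is not a declared region")
            if s == rid:
                raise GraphError(f"self-loop at region {rid!r}")
            if rid not in listed[s]:
                asym = True
            edges.add(tuple(sorted((rid, s))))
    if asym:
        warnings.warn("asymmetric adjacency input; symmetrizing", stacklevel=2)
    return RegionGraph.from_edges(regions, sorted(edges))


def write_adjacency(graph: RegionGraph, path: str | Path) -> None:
    lines = [str(graph.n_regions)]
    for r in graph.regions:
        nbrs = sorted(graph.neighbors[r])
        toks = [r.replace(" ", "_"), str(len(nbrs))] + [s.replace(" ", "_") for s in nbrs]
        lines.append(" ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("geoadd").joinpath("data", name)))


def nigeria_graph(merged: bool = True) -> RegionGraph:
    """The Nigeria state adjacency graph.

    With ``merged=True`` (default) returns the 31 analysis regions (pre-1996
    30 states + Abuja, post-1996 splits re-merged); otherwise the raw
    37-state graph.
    """
    raw = read_adjacency(_data_path("nigeria_states_37.txt"))
    if not merged:
        return raw
    g = raw.merge(MERGED_PAIRS)
    # keep the canonical region order (reference region first)
    order = [r for r in NIGERIA_REGIONS if r in g.regions]
    edges = [(r, s) for r in order for s in g.neighbors[r] if r < s]
    return RegionGraph.from_edges(order, edges)
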