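"""GIS-style macroscale walkability components, index, and stratification.

The four components are net residential density (housing units per
residential parcel area), land-use mix (normalized Shannon entropy over
seven parcel land-use categories: 0 = single use, 1 = even distribution),
intersection density (count of three-leg-or-more intersections in the
buffer), and transit access (stops in the buffer).  The walkability index
is the sum of the four components' sample z-scores, making it invariant
to affine rescaling of any raw component.

Stratification mirrors a two-way decile design: SES deciles 1-5 are
"lower SES" and 7-10 "higher SES" with the 6th omitted; walkability
deciles 1-4 are "lower walkable" and 7-10 "higher walkable" with the 5th
and 6th excluded — both exclusions reduce boundary mis-categorization.
"""

from __future__ import annotations

import ast
import dataclasses
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from walkaudit.features import LAND_USE_CATEGORIES
from walkaudit.neighborhood import zscore_across_sample

COMPONENTS = ("net_residential_density", "land_use_mix", "intersection_density", "transit_access")


def land_use_mix(areas: Mapping[str, float] | Iterable[float]) -> float:
    """Normalized Shannon entropy -sum(p ln p) / ln(7) over the seven
    land-use categories; zero-area categories contribute 0."""
    if isinstance(areas, Mapping):
        vec = np.array([float(areas.get(c, 0.0)) for c in LAND_USE_CATEGORIES])
    else:
        vec = np.asarray(list(areas), dtype=float)
        if vec.size != len(LAND_USE_CATEGORIES):
            raise ValueError(f"expected {len(LAND_USE_CATEGORIES)} category areas, got {vec.size}")
    if (vec < 0).any():
        raise ValueError("areas must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("total parcel area must be positive")
    p = vec / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(LAND_USE_CATEGORIES)))


def net_residential_density(housing_units: float, residential_parcel_area: float) -> float:
    """Housing units divided by residential parcel land area."""
    if housing_units < 0 or residential_parcel_area < 0:
        raise ValueError("inputs must be non-negative")
    if residential_parcel_area == 0:
        if housing_units == 0:
            return float("nan")
        raise ValueError("nonzero housing units on zero residential area")
    return housing_units / residential_parcel_area


def intersection_count(graph: nx.Graph, buffer_nodes: Iterable) -> int:
    """Number of three-leg-or-more intersections among the buffer nodes."""
    count = 0
    for node in buffer_nodes:
        n = ast.literal_eval(node) if isinstance(node, str) else node
        if n not in graph:
            raise KeyError(f"buffer node {node} not in street graph")
        if graph.degree[n] >= 3:
            count += 1
    return count


def walkability_index(components: pd.DataFrame) -> pd.DataFrame:
    """z-score each of the four components across the sample (n-1 SD) and
    sum them into the walkability index.

    Input needs the four columns in :data:`COMPONENTS`; returns a copy
    with z_<component> columns and ``walkability_index`` added.
    """
    missing = [c for c in COMPONENTS if c not in components.columns]
    if missing:
        raise ValueError(f"missing component columns: {missing}")
    if len(components) < 2:
        raise ValueError("need >= 2 units to z-score components")
    out = components.copy()
    for c in COMPONENTS:
        out[f"z_{c}"] = zscore_across_sample(out[c], name=c).to_numpy()
    out["walkability_index"] = sum(out[f"z_{c}"] for c in COMPONENTS)
    return out


def deciles(values: pd.Series) -> np.ndarray:
    """Decile (1-10) of each value, with average ranks for ties."""
    v = np.asarray(values, dtype=float)
    r = rankdata(v, method="average")
    d = np.ceil(10 * r / len(v)).astype(int)
    return np.clip(d, 1, 10)


@dataclasses.dataclass(frozen=True)
class StratumAssignment:
    block_group_id: str
    ses_decile: int
    walk_decile: int
    stratum: str | None  # None = excluded


def stratify(ses: pd.Series, walkability: pd.Series) -> pd.DataFrame:
    """Cross-classify units into the four SES x walkability strata.

    SES deciles 1-5 lower / 7-10 higher, 6 excluded; walkability deciles
    1-4 lower / 7-10 higher, 5-6 excluded.  Excluded units get stratum
    None.  Index alignment of the two series identifies the units.
    """
    if len(ses) != len(walkability):
        raise ValueError("ses and walkability must align")
    if len(ses) < 10:
        raise ValueError("need >= 10 units to form deciles")
    sd = deciles(ses)
    wd = deciles(walkability)
    strata = []
    for s, w in zip(sd, wd):
        ses_cat = "loSES" if s <= 5 else ("hiSES" if s >= 7 else None)
        walk_cat = "loWalk" if w <= 4 else ("hiWalk" if w >= 7 else None)
        strata.append(f"{ses_cat}/{walk_cat}" if ses_cat and walk_cat else None)
    return pd.DataFrame(
        {"ses_decile": sd, "walk_decile": wd, "stratum": strata},
        index=ses.index,
    )


def macro_components_for_participants(
    region,
    participants: pd.DataFrame,
    radius: float = 500.0,
) -> pd.DataFrame:
    """Individual-level macroscale components for each participant.

    Intersection density is counted inside the participant's street-
    network buffer; density, land-use mix and transit access come from the
    home block group's attribute table (the simulator's attributes are
    block-group level).
    """
    import networkx as nx  # local alias for clarity

    bg = region.block_groups.set_index("block_group_id")
    rows = []
    for rec in participants.itertuples(index=False):
        home = ast.literal_eval(rec.home_node)
        dist = nx.single_source_dijkstra_path_length(region.graph, home, cutoff=radius, weight="length")
        n_int = sum(1 for node, d in dist.items() if region.graph.degree[node] >= 3)
        attrs = bg.loc[rec.block_group]
        areas = {c: attrs[f"area_{c}"] for c in LAND_USE_CATEGORIES}
        rows.append(
            {
                "participant_id": rec.participant_id,
                "net_residential_density": net_residential_density(
                    attrs["housing_units"], attrs[f"area_{LAND_USE_CATEGORIES[0]}"]
                ),
                "land_use_mix": land_use_mix(areas),
                "intersection_density": n_int,
                "transit_access": attrs["transit_stops"],
            }
        )
    return walkability_index(pd.DataFrame(rows))


def macro_components_for_block_groups(region) -> pd.DataFrame:
    """Block-group level components and index (used for stratification)."""
    inter = (
        region.coordinates[region.coordinates["type"] == "intersection"]
        .groupby("block_group")
        .size()
        .rename("intersection_density")
    )
    bg = region.block_groups.set_index("block_group_id")
    df = pd.DataFrame(
        {
            "net_residential_density": bg["housing_units"] / bg[f"area_{LAND_USE_CATEGORIES[0]}"],
            "land_use_mix": [
                land_use_mix({c: bg.loc[i, f"area_{c}"] for c in LAND_USE_CATEGORIES}) for i in bg.index
            ],
            "intersection_density": inter.reindex(bg.index).fillna(0).astype(int),
            "transit_access": bg["transit_stops"],
        },
        index=bg.index,
    )
    return walkability_index(df)
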