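"""Synthetic street networks, participants, and planted ground truth.

Emulates the sampling frame of a neighborhood-walkability study: a
perturbed rectangular grid street network (Phoenix-like morphology) whose
nodes are partitioned into block groups; audit coordinates at intersections
(nodes of degree >= 3) and at segment midpoints; a latent walkability
factor per block group that drives (a) per-coordinate streetscape-feature
presence through a logistic model, (b) macroscale block-group attributes
(housing, land-use balance, transit), and (c) most perceived-walkability
subscales.  Traffic-safety and crime-safety perceptions are generated
independent of the latent factor so that null correlations are testable.

All ground truth (the latent factor, planted presence, expected rates) is
returned to the caller, which is what makes recovery properties checkable.
"""

from __future__ import annotations

import ast
import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from walkaudit.features import LAND_USE_CATEGORIES, PRIMITIVE_FEATURES, StreetFeature

HEADINGS = (0, 90, 180, 270)

#: Baseline per-feature presence rates: the model-detected neighborhood
#: prevalences reported for the Phoenix study region.
DEFAULT_BASELINE_RATES: dict[StreetFeature, float] = {
    StreetFeature.SIDEWALK: 0.898,
    StreetFeature.STREETLIGHT: 0.315,
    StreetFeature.CURB_CUT: 0.262,
    StreetFeature.SIDEWALK_BUFFER: 0.159,
    StreetFeature.LINE_CROSSWALK: 0.049,
    StreetFeature.WALK_SIGNAL: 0.037,
    StreetFeature.BIKE_SYMBOL: 0.005,
    StreetFeature.ZEBRA_CROSSWALK: 0.003,
}

#: Default loadings of each feature on the latent walkability factor
#: (log-odds change per SD of latent walkability); moderate positive
#: values so that better streetscapes co-occur with walkable macro form.
DEFAULT_LOADINGS: dict[StreetFeature, float] = {
    StreetFeature.SIDEWALK: 1.0,
    StreetFeature.SIDEWALK_BUFFER: 0.8,
    StreetFeature.CURB_CUT: 0.8,
    StreetFeature.ZEBRA_CROSSWALK: 0.7,
    StreetFeature.LINE_CROSSWALK: 0.7,
    StreetFeature.WALK_SIGNAL: 0.9,
    StreetFeature.BIKE_SYMBOL: 0.7,
    StreetFeature.STREETLIGHT: 0.9,
}

PERCEIVED_SUBSCALES = (
    "residential_density",
    "land_use_mix",
    "street_connectivity",
    "walking_cycling_facilities",
    "aesthetics",
    "traffic_safety",
    "crime_safety",
)


@dataclasses.dataclass(frozen=True)
class RegionConfig:
    """Shape of the simulated region.

    ``grid_rows x grid_cols`` street-network nodes connected as a grid with
    ``edge_length`` meters per edge; block groups tile the grid in
    ``bg_rows x bg_cols`` rectangles.
    """

    grid_rows: int = 25
    grid_cols: int = 25
    edge_length: float = 100.0
    bg_rows: int = 5
    bg_cols: int = 5
    position_jitter: float = 0.1  # visual-only node displacement, x edge_length

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.bg_rows < 1 or self.bg_cols < 1:
            raise ValueError("block-group tiling must be positive")


@dataclasses.dataclass
class SyntheticRegion:
    """A simulated study region with street graph, audit coordinates, and
    block-group attribute table (including the latent walkability factor
    as ground truth)."""

    graph: nx.Graph
    coordinates: pd.DataFrame  # coordinate_id, type, x, y, node/u/v, block_group
    block_groups: pd.DataFrame  # block_group_id, latent_walkability, ses, attrs
    config: RegionConfig
    seed: int

    def intersection_ids(self) -> pd.Index:
        return self.coordinates.loc[self.coordinates["type"] == "intersection", "coordinate_id"]


def _block_group_of(cfg: RegionConfig, i: int, j: int) -> str:
    bi = min(i * cfg.bg_rows // cfg.grid_rows, cfg.bg_rows - 1)
    bj = min(j * cfg.bg_cols // cfg.grid_cols, cfg.bg_cols - 1)
    return f"bg_{bi:02d}_{bj:02d}"


def simulate_region(config: RegionConfig, seed: int) -> SyntheticRegion:
    """Build the street graph, audit coordinates, and block-group table.

    Deterministic per ``(config, seed)``.  Intersection coordinates sit on
    nodes of degree >= 3 (grid corners, degree 2, are excluded); one
    segment coordinate sits at each edge midpoint.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    cfg = config
    g = nx.grid_2d_graph(cfg.grid_rows, cfg.grid_cols)
    for (i, j) in g.nodes:
        jx, jy = rng.uniform(-cfg.position_jitter, cfg.position_jitter, 2) * cfg.edge_length
        g.nodes[(i, j)]["pos"] = (j * cfg.edge_length + jx, i * cfg.edge_length + jy)
        g.nodes[(i, j)]["block_group"] = _block_group_of(cfg, i, j)
    for u, v in g.edges:
        g.edges[u, v]["length"] = cfg.edge_length

    rows = []
    for node in sorted(g.nodes):
        if g.degree[node] >= 3:
            x, y = g.nodes[node]["pos"]
            rows.append(
                {
                    "coordinate_id": f"int_{node[0]:03d}_{node[1]:03d}",
                    "type": "intersection",
                    "x": x,
                    "y": y,
                    "node": str(node),
                    "u": "",
                    "v": "",
                    "block_group": g.nodes[node]["block_group"],
                }
            )
    for u, v in sorted(g.edges):
        xu, yu = g.nodes[u]["pos"]
        xv, yv = g.nodes[v]["pos"]
        rows.append(
            {
                "coordinate_id": f"seg_{u[0]:03d}_{u[1]:03d}__{v[0]:03d}_{v[1]:03d}",
                "type": "segment",
                "x": (xu + xv) / 2,
                "y": (yu + yv) / 2,
                "node": "",
                "u": str(u),
                "v": str(v),
                "block_group": g.nodes[u]["block_group"],
            }
        )
    coordinates = pd.DataFrame(rows)

    bg_ids = sorted({g.nodes[n]["block_group"] for n in g.nodes})
    # Latent walkability is a spatially smooth field: adjacent block groups
    # resemble each other (exponential-kernel Gaussian process over block
    # group centroids, range = two block-group widths), as in real urban
    # form.  SES is drawn the same way but independently of walkability.
    centers = np.array(
        [
            (
                (int(b.split("_")[1]) + 0.5) * cfg.grid_rows / cfg.bg_rows,
                (int(b.split("_")[2]) + 0.5) * cfg.grid_cols / cfg.bg_cols,
            )
            for b in bg_ids
        ]
    )
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    scale = 2.0 * max(cfg.grid_rows / cfg.bg_rows, cfg.grid_cols / cfg.bg_cols)
    cov = np.exp(-d / scale) + 1e-9 * np.eye(len(bg_ids))
    chol = np.linalg.cholesky(cov)
    latent = chol @ rng.normal(0.0, 1.0, len(bg_ids))
    ses = chol @ rng.normal(0.0, 1.0, len(bg_ids))  # independent of walkability
    bg_rows = []
    for bg, L, S in zip(bg_ids, latent, ses):
        total_area = float(rng.lognormal(mean=np.log(2.0e5), sigma=0.2))  # m^2
        # land-use balance rises with latent walkability: interpolate
        # between a single-use profile and the uniform profile
        t = 1.0 / (1.0 + np.exp(-(0.9 * L + rng.normal(0, 0.4))))
        single = np.zeros(len(LAND_USE_CATEGORIES))
        single[0] = 1.0
        shares = (1 - t) * single + t * np.full(len(LAND_USE_CATEGORIES), 1 / len(LAND_USE_CATEGORIES))
        res_area = max(total_area * shares[0], 1.0)
        housing = int(rng.poisson(res_area / 500.0 * np.exp(0.5 * L + rng.normal(0, 0.2))))
        row = {
            "block_group_id": bg,
            "latent_walkability": L,
            "median_income": float(60_000 * np.exp(0.35 * S + rng.normal(0, 0.1))),
            "housing_units": housing,
            "transit_stops": int(rng.poisson(np.exp(1.3 + 0.6 * L))),
        }
        for cat, share in zip(LAND_USE_CATEGORIES, shares):
            row[f"area_{cat}"] = float(total_area * share)
        bg_rows.append(row)
    block_groups = pd.DataFrame(bg_rows)

    return SyntheticRegion(graph=g, coordinates=coordinates, block_groups=block_groups, config=cfg, seed=seed)


def sample_participants(region: SyntheticRegion, n: int, seed: int) -> pd.DataFrame:
    """Place ``n`` participant homes uniformly on street-graph nodes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))
    nodes = sorted(region.graph.nodes)
    idx = rng.integers(0, len(nodes), size=n)
    return pd.DataFrame(
        {
            "participant_id": [f"p_{i:04d}" for i in range(n)],
            "home_node": [str(nodes[k]) for k in idx],
            "block_group": [region.graph.nodes[nodes[k]]["block_group"] for k in idx],
        }
    )


def network_buffer(region: SyntheticRegion, home_node, radius: float) -> set[str]:
    """Audit coordinates within network distance ``radius`` of a home node.

    Intersection coordinates are measured to their node; segment
    coordinates to the edge midpoint (shorter approach from either end).
    A disconnected home yields only coordinates on its component.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    node = ast.literal_eval(home_node) if isinstance(home_node, str) else home_node
    if node not in region.graph:
        raise KeyError(f"home node {home_node} not in street graph")
    dist = nx.single_source_dijkstra_path_length(region.graph, node, cutoff=radius, weight="length")
    members: set[str] = set()
    coords = region.coordinates
    for row in coords.itertuples(index=False):
        if row.type == "intersection":
            d = dist.get(ast.literal_eval(row.node), np.inf)
        else:
            u, v = ast.literal_eval(row.u), ast.literal_eval(row.v)
            half = region.graph.edges[u, v]["length"] / 2
            d = min(dist.get(u, np.inf) + half, dist.get(v, np.inf) + half)
        if d <= radius:
            members.add(row.coordinate_id)
    return members


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth planted into a region.

    ``presence`` is coordinate x feature booleans; ``expected_rate`` the
    corresponding logistic probabilities; ``directional`` maps which of the
    four headings show the feature when it is present (a present feature
    appears in >= 1 of the 4 directional scenes, >= 2 for sidewalks so the
    mean-then-threshold rule is exercised).
    """

    latent: pd.Series  # per block group
    loadings: dict[StreetFeature, float]
    baseline_rates: dict[StreetFeature, float]
    presence: pd.DataFrame  # index coordinate_id, one bool column per feature
    expected_rate: pd.DataFrame  # same shape, float
    directional: pd.DataFrame  # index (coordinate_id, feature), bool col per heading


def plant_prevalences(
    region: SyntheticRegion,
    loadings: dict[StreetFeature, float] | None = None,
    baseline_rates: dict[StreetFeature, float] | None = None,
    seed: int = 0,
) -> PlantedTruth:
    """Draw per-coordinate feature presence from the logistic model
    ``P(present) = sigmoid(logit(baseline) + loading * latent)``.

    Sidewalk-buffer truth is forced absent wherever sidewalk truth is
    absent (a buffer strip cannot exist without a sidewalk).
    """
    loadings = dict(DEFAULT_LOADINGS if loadings is None else loadings)
    baseline_rates = dict(DEFAULT_BASELINE_RATES if baseline_rates is None else baseline_rates)
    for f, p in baseline_rates.items():
        if not 0.0 < p < 1.0:
            raise ValueError(f"baseline rate for {f} must be in (0, 1), got {p}")
    rng = np.random.default_rng(int(seed) % (2**31))
    latent = region.block_groups.set_index("block_group_id")["latent_walkability"]
    coord_latent = region.coordinates["block_group"].map(latent).to_numpy()
    coord_ids = region.coordinates["coordinate_id"].to_numpy()

    presence = {}
    expected = {}
    for f in PRIMITIVE_FEATURES:
        alpha = np.log(baseline_rates[f] / (1 - baseline_rates[f]))
        p = 1.0 / (1.0 + np.exp(-(alpha + loadings[f] * coord_latent)))
        presence[f.value] = rng.uniform(size=len(p)) < p
        expected[f.value] = p
    presence[StreetFeature.SIDEWALK_BUFFER.value] &= presence[StreetFeature.SIDEWALK.value]

    pres_df = pd.DataFrame(presence, index=coord_ids)
    exp_df = pd.DataFrame(expected, index=coord_ids)

    # Directional visibility draws.  A present feature shows in >= 1 of the
    # 4 headings; sidewalks in >= 2 (exercises the mean rule); a visible
    # sidewalk buffer only shows in headings where the sidewalk shows too,
    # so every directional image is a renderable scene.
    dir_rows = []
    for ci, cid in enumerate(coord_ids):
        sidewalk_vis = np.zeros(4, dtype=bool)
        for f in PRIMITIVE_FEATURES:
            vis = np.zeros(4, dtype=bool)
            if pres_df.at[cid, f.value]:
                if f == StreetFeature.SIDEWALK:
                    nd = rng.integers(2, 5)
                    vis[rng.choice(4, size=nd, replace=False)] = True
                    sidewalk_vis = vis
                elif f == StreetFeature.SIDEWALK_BUFFER:
                    slots = np.flatnonzero(sidewalk_vis)
                    nd = rng.integers(1, len(slots) + 1)
                    vis[rng.choice(slots, size=nd, replace=False)] = True
                else:
                    nd = rng.integers(1, 5)
                    vis[rng.choice(4, size=nd, replace=False)] = True
            dir_rows.append(
                {"coordinate_id": cid, "feature": f.value, **{f"h{h}": bool(b) for h, b in zip(HEADINGS, vis)}}
            )
    directional = pd.DataFrame(dir_rows).set_index(["coordinate_id", "feature"])

    return PlantedTruth(
        latent=latent,
        loadings=loadings,
        baseline_rates=baseline_rates,
        presence=pres_df,
        expected_rate=exp_df,
        directional=directional,
    )


def oracle_directional_probs(truth: PlantedTruth) -> pd.DataFrame:
    """Directional probability table as produced by perfect classifiers:
    probability 1.0 where the feature is visible at that heading, else 0.0.

    Long format: coordinate_id, feature, h0/h90/h180/h270 probabilities.
    """
    probs = truth.directional.astype(float)
    return probs.reset_index()


def simulate_perceptions(
    truth: PlantedTruth,
    region: SyntheticRegion,
    participants: pd.DataFrame,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant perceived-walkability responses.

    Each subscale is a standardized monotone transform of its planted
    driver plus Gaussian noise with SD ``noise_sd``.  Traffic-safety and
    crime-safety are pure noise (independent of latent walkability), so
    their pipeline correlations are testable nulls.  Per-feature item
    responses are driven by the home block group's planted feature rate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(int(seed) % (2**31))
    bg = region.block_groups.set_index("block_group_id")
    pbg = participants["block_group"]

    def standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    res_density = (bg["housing_units"] / bg[[f"area_{c}" for c in LAND_USE_CATEGORIES[:1]]].iloc[:, 0]).reindex(pbg).to_numpy()
    area_cols = bg[[f"area_{c}" for c in LAND_USE_CATEGORIES]]
    shares = area_cols.div(area_cols.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(shares * np.log(shares.where(shares > 0, 1.0))).sum(axis=1) / np.log(len(LAND_USE_CATEGORIES))
    lum = ent.reindex(pbg).to_numpy()
    latent_p = truth.latent.reindex(pbg).to_numpy()
    # street connectivity driver: intersections per block group
    inter = region.coordinates[region.coordinates["type"] == "intersection"].groupby("block_group").size()
    conn = inter.reindex(pbg).fillna(0).to_numpy()

    n = len(participants)
    drivers = {
        "residential_density": standardize(res_density),
        "land_use_mix": standardize(lum),
        "street_connectivity": standardize(conn.astype(float)),
        "walking_cycling_facilities": standardize(latent_p),
        "aesthetics": standardize(latent_p),
        "traffic_safety": rng.normal(0, 1, n),
        "crime_safety": rng.normal(0, 1, n),
    }
    out = {"participant_id": participants["participant_id"].to_numpy()}
    for name in PERCEIVED_SUBSCALES:
        out[name] = drivers[name] + rng.normal(0, noise_sd, n)
    for f in PRIMITIVE_FEATURES:
        rate = truth.expected_rate[f.value]
        bg_rate = pd.Series(rate.to_numpy(), index=region.coordinates["block_group"].to_numpy()).groupby(level=0).mean()
        out[f"item_{f.value}"] = standardize(bg_rate.reindex(pbg).to_numpy()) + rng.normal(0, noise_sd, n)
    return pd.DataFrame(out)


def write_region(region: SyntheticRegion, out_dir: str | Path) -> None:
    """Export region tables as CSV (nodes, edges, coordinates, block groups)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            {"node": str(n), "x": d["pos"][0], "y": d["pos"][1], "block_group": d["block_group"], "degree": region.graph.degree[n]}
            for n, d in sorted(region.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [{"u": str(u), "v": str(v), "length": d["length"]} for u, v, d in sorted(region.graph.edges(data=True))]
    )
    nodes.to_csv(out / "nodes.csv", index=False)
    edges.to_csv(out / "edges.csv", index=False)
    region.coordinates.to_csv(out / "coordinates.csv", index=False)
    region.block_groups.to_csv(out / "block_groups.csv", index=False)
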