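"""Region simulation: grid topology, buffers, planted truth, perceptions."""

import ast

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from walkaudit.features import PRIMITIVE_FEATURES, StreetFeature
from walkaudit.geosim import (
    DEFAULT_BASELINE_RATES,
    RegionConfig,
    network_buffer,
    plant_prevalences,
    sample_participants,
    simulate_perceptions,
    simulate_region,
)


class TestSimulateRegion:
    def test_grid_node_edge_counts(self):
        region = simulate_region(RegionConfig(grid_rows=5, grid_cols=5, bg_rows=1, bg_cols=1), seed=0)
        assert region.graph.number_of_nodes() == 25
        assert region.graph.number_of_edges() == 40  # 2*n*(n-1) for square grid

    def test_two_by_two_has_no_intersections(self):
        region = simulate_region(RegionConfig(grid_rows=2, grid_cols=2, bg_rows=1, bg_cols=1), seed=0)
        assert (region.coordinates["type"] == "intersection").sum() == 0
        assert (region.coordinates["type"] == "segment").sum() == 4

    def test_intersections_have_degree_three_plus(self, small_region):
        for rec in small_region.coordinates.itertuples(index=False):
            if rec.type == "intersection":
                assert small_region.graph.degree[ast.literal_eval(rec.node)] >= 3

    def test_segment_coordinates_at_edge_midpoints(self, small_region):
        g = small_region.graph
        segs = small_region.coordinates[small_region.coordinates["type"] == "segment"]
        for rec in segs.itertuples(index=False):
            u, v = ast.literal_eval(rec.u), ast.literal_eval(rec.v)
            xu, yu = g.nodes[u]["pos"]
            xv, yv = g.nodes[v]["pos"]
            assert rec.x == pytest.approx((xu + xv) / 2)
            assert rec.y == pytest.approx((yu + yv) / 2)

    def test_positive_edge_lengths(self, small_region):
        assert all(d["length"] > 0 for _, _, d in small_region.graph.edges(data=True))

    def test_deterministic(self):
        cfg = RegionConfig(grid_rows=6, grid_cols=6, bg_rows=2, bg_cols=2)
        a = simulate_region(cfg, seed=3)
        b = simulate_region(cfg, seed=3)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        pd.testing.assert_frame_equal(a.block_groups, b.block_groups)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            RegionConfig(grid_rows=1, grid_cols=5)
        with pytest.raises(ValueError):
            RegionConfig(edge_length=-1.0)


class TestNetworkBuffer:
    def test_radius_zero_contains_only_home(self, small_region):
        home = "(4, 4)"  # interior node, degree 4
        members = network_buffer(small_region, home, 0.0)
        expected = {f"int_004_004"}
        assert members == expected

    def test_matches_exhaustive_dijkstra(self, small_region):
        """Buffer membership equals a brute-force shortest-path check."""
        g = small_region.graph
        home = (2, 3)
        radius = 2.0 * small_region.config.edge_length
        dist = dict(nx.single_source_dijkstra_path_length(g, home, weight="length"))
        expected = set()
        for rec in small_region.coordinates.itertuples(index=False):
            if rec.type == "intersection":
                d = dist.get(ast.literal_eval(rec.node), np.inf)
            else:
                u, v = ast.literal_eval(rec.u), ast.literal_eval(rec.v)
                half = g.edges[u, v]["length"] / 2
                d = min(dist.get(u, np.inf), dist.get(v, np.inf)) + half
            if d <= radius:
                expected.add(rec.coordinate_id)
        assert network_buffer(small_region, str(home), radius) == expected

    def test_saturation_at_graph_diameter(self, small_region):
        members = network_buffer(small_region, "(0, 0)", 1e9)
        assert members == set(small_region.coordinates["coordinate_id"])

    def test_monotone_in_radius(self, small_region):
        home = "(3, 3)"
        radii = [0, 100, 250, 400, 800]
        buffers = [network_buffer(small_region, home, r) for r in radii]
        for smaller, larger in zip(buffers, buffers[1:]):
            assert smaller <= larger

    def test_unknown_home_rejected(self, small_region):
        with pytest.raises(KeyError):
            network_buffer(small_region, "(99, 99)", 100.0)


class TestPlantPrevalences:
    def test_zero_loadings_recover_baseline(self, small_region):
        loadings = {f: 0.0 for f in PRIMITIVE_FEATURES}
        rates = {f: 0.4 for f in PRIMITIVE_FEATURES}
        truth = plant_prevalences(small_region, loadings, rates, seed=21)
        # curb cut is unconditional: empirical prevalence ~ Binomial(n, 0.4)
        emp = truth.presence["curb_cut"].mean()
        n = len(truth.presence)
        assert abs(emp - 0.4) < 3 * np.sqrt(0.4 * 0.6 / n)

    def test_positive_loading_is_monotone_in_latent(self, small_region):
        loadings = {f: 0.0 for f in PRIMITIVE_FEATURES}
        loadings[StreetFeature.SIDEWALK] = 2.0
        rates = {f: 0.5 for f in PRIMITIVE_FEATURES}
        truth = plant_prevalences(small_region, loadings, rates, seed=22)
        lat = small_region.coordinates["block_group"].map(truth.latent)
        hi = truth.presence["sidewalk"].to_numpy()[lat.to_numpy() >= lat.quantile(0.75)]
        lo = truth.presence["sidewalk"].to_numpy()[lat.to_numpy() <= lat.quantile(0.25)]
        assert hi.mean() > lo.mean()

    def test_buffer_truth_requires_sidewalk_truth(self, small_truth):
        p = small_truth.presence
        assert not (p["sidewalk_buffer"] & ~p["sidewalk"]).any()

    def test_law_of_large_numbers_recovery(self):
        """Mean planted presence approaches the logistic expectation."""
        region = simulate_region(RegionConfig(grid_rows=27, grid_cols=27, bg_rows=3, bg_cols=3), seed=30)
        truth = plant_prevalences(region, seed=31)
        assert len(truth.presence) >= 2000
        for f in PRIMITIVE_FEATURES:
            emp = truth.presence[f.value].mean()
            exp = truth.expected_rate[f.value].mean()
            if f == StreetFeature.SIDEWALK_BUFFER:
                # conditional forcing lowers the marginal below the logistic rate
                assert emp <= exp + 0.02
            else:
                assert abs(emp - exp) < 0.02

    def test_directional_visibility_conventions(self, small_truth):
        d = small_truth.directional
        hcols = [c for c in d.columns]
        counts = d[hcols].sum(axis=1)
        pres = small_truth.presence
        for (cid, feat), n_vis in counts.items():
            present = pres.at[cid, feat]
            if not present:
                assert n_vis == 0
            elif feat == "sidewalk":
                assert n_vis >= 2
            else:
                assert n_vis >= 1
        # visible buffer only where sidewalk is visible in the same heading
        sw = d.xs("sidewalk", level="feature")
        bf = d.xs("sidewalk_buffer", level="feature")
        assert not (bf & ~sw.loc[bf.index]).any().any()

    def test_invalid_baseline_rate_rejected(self, small_region):
        rates = dict(DEFAULT_BASELINE_RATES)
        rates[StreetFeature.SIDEWALK] = 1.0
        with pytest.raises(ValueError, match="baseline"):
            plant_prevalences(region=small_region, baseline_rates=rates, seed=0)


class TestSimulatePerceptions:
    def test_noiseless_subscale_rank_correlates_perfectly(self, small_region, small_truth, small_participants):
        from walkaudit.evalstats import spearman

        perc = simulate_perceptions(small_truth, small_region, small_participants, noise_sd=0.0, seed=41)
        driver = small_truth.latent.reindex(small_participants["block_group"]).to_numpy()
        rho, _ = spearman(perc["walking_cycling_facilities"], driver)
        assert rho == pytest.approx(1.0)

    def test_huge_noise_destroys_correlation(self, small_region, small_truth, small_participants):
        from walkaudit.evalstats import spearman

        perc = simulate_perceptions(small_truth, small_region, small_participants, noise_sd=1e6, seed=42)
        driver = small_truth.latent.reindex(small_participants["block_group"]).to_numpy()
        rho, _ = spearman(perc["walking_cycling_facilities"], driver)
        assert abs(rho) < 0.5  # n=40; pure noise band

    def test_crime_safety_independent_of_latent(self, small_region, small_truth):
        """Over repeated draws the crime-safety subscale stays in the null
        correlation band around zero."""
        from walkaudit.evalstats import spearman

        parts = sample_participants(small_region, 200, seed=50)
        driver = small_truth.latent.reindex(parts["block_group"]).to_numpy()
        inside = 0
        n_seeds = 20
        for s in range(n_seeds):
            perc = simulate_perceptions(small_truth, small_region, parts, noise_sd=1.0, seed=1000 + s)
            rho, _ = spearman(perc["crime_safety"], driver)
            inside += abs(rho) < 0.2
        assert inside >= n_seeds - 1

    def test_negative_noise_rejected(self, small_region, small_truth, small_participants):
        with pytest.raises(ValueError):
            simulate_perceptions(small_truth, small_region, small_participants, noise_sd=-1.0, seed=0)
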