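"""Candidate graphs and exact ILP tracking: scoring formulas, solver vs
brute-force oracle, fusion extraction and cell tracklets."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from organomorph import tracking
from organomorph.synthgen import _ball_mask


def manual_graph(node_specs, edge_specs, **param_overrides):
    """node_specs: {(frame, id): score}; edge_specs: {(u, v): score}."""
    g = nx.DiGraph()
    for (t, i), score in node_specs.items():
        g.add_node((t, i), frame=t, label=i, centroid=(0.0, 0.0, 0.0),
                   volume_um3=1.0, score=score)
    for (u, v), score in edge_specs.items():
        g.add_edge(u, v, score=score)
    params = tracking.TrackingParams(**param_overrides)
    return tracking.CandidateGraph(graph=g, params=params)


class TestBuildGraph:
    def test_node_score_formula(self):
        movie = np.zeros((1, 10, 20, 20), dtype=np.uint16)
        movie[0, 2:6, 2:12, 2:12] = 1  # 400 voxels
        movie[0, 7:9, 14:19, 14:19] = 2  # 50 voxels
        params = tracking.lumen_params(min_vol_um3=200.0)
        cg = tracking.build_graph(movie, (1, 1, 1), params)
        assert cg.graph.nodes[(0, 1)]["score"] == pytest.approx(0.5)
        # volume == min_vol -> score 0
        params2 = tracking.lumen_params(min_vol_um3=50.0)
        cg2 = tracking.build_graph(movie, (1, 1, 1), params2)
        assert cg2.graph.nodes[(0, 2)]["score"] == pytest.approx(0.0)

    def test_identical_masks_full_overlap_edge(self):
        frame = np.zeros((12, 24, 24), dtype=np.uint16)
        frame[2:10, 4:20, 4:20] = 1
        movie = np.stack([frame, frame])
        cg = tracking.build_graph(movie, (1, 1, 1),
                                  tracking.lumen_params(min_vol_um3=10.0))
        assert cg.graph.edges[(0, 1), (1, 1)]["score"] == pytest.approx(1.0)

    def test_cell_edge_zero_at_max_distance_removed(self):
        movie = np.zeros((2, 8, 8, 60), dtype=np.uint16)
        movie[0, 2:6, 2:6, 2:6] = 1
        movie[1, 2:6, 2:6, 52:56] = 1  # exactly 50 um away, no overlap
        params = tracking.cell_params(
            max_dist_um=50.0, min_mask_vol_um3=0.0, min_vol_um3=1.0
        )
        cg = tracking.build_graph(movie, (1, 1, 1), params)
        # score = 0.5 * ((1 - d/max) + IOU) = 0.5 * (0 + 0) -> removed
        assert cg.graph.number_of_edges() == 0
        # a closer, overlapping pair keeps its edge
        movie[1] = np.roll(movie[0], 2, axis=2)
        cg2 = tracking.build_graph(movie, (1, 1, 1), params)
        assert cg2.graph.number_of_edges() == 1

    def test_cell_mode_drops_small_masks(self):
        movie = np.zeros((1, 16, 16, 32), dtype=np.uint16)
        movie[0, 2:13, 2:13, 2:14] = 1  # 1452 voxels -> kept
        movie[0, 2:13, 2:13, 18:30] = 2
        movie[0, 2, 2, 18:30] = 0  # trim to 1440 voxels -> dropped
        params = tracking.cell_params(min_mask_vol_um3=1444.0,
                                      min_vol_um3=481.6)
        cg = tracking.build_graph(movie, (1, 1, 1), params)
        assert (0, 1) in cg.graph.nodes
        assert (0, 2) not in cg.graph.nodes

    def test_rejects_non_movie_input(self):
        with pytest.raises(ValueError):
            tracking.build_graph(np.zeros((4, 4, 4), dtype=np.uint16),
                                 (1, 1, 1), tracking.lumen_params())


class TestSolve:
    def test_merge_fixture_selects_fusion(self):
        # two parents merging into one child; generous overlaps
        cg = manual_graph(
            {(0, 1): 0.5, (0, 2): 0.5, (1, 1): 0.5, (2, 1): 0.5,
             (2, 2): 0.5},
            {((0, 1), (1, 1)): 0.9, ((0, 2), (1, 1)): 0.8,
             ((1, 1), (2, 1)): 0.9, ((1, 1), (2, 2)): 0.7},
            appear_cost=0.8, disappear_cost=0.8,
            max_children=2, max_parents=2,
        )
        sol = tracking.solve(cg)
        tracking.audit_solution(sol)
        oracle = tracking.brute_force_solve(cg)
        assert sol.objective == pytest.approx(oracle.objective)
        assert ((0, 1), (1, 1)) in sol.edges
        assert ((0, 2), (1, 1)) in sol.edges
        assert sol.fusions == [(1, 1)]

    def test_single_chain_has_no_events(self):
        cg = manual_graph(
            {(0, 1): 0.5, (1, 1): 0.5, (2, 1): 0.5},
            {((0, 1), (1, 1)): 0.9, ((1, 1), (2, 1)): 0.9},
        )
        sol = tracking.solve(cg)
        assert sol.nodes == {(0, 1), (1, 1), (2, 1)}
        assert not sol.appearances and not sol.disappearances

    def test_isolated_negative_node_unselected(self):
        cg = manual_graph({(0, 1): -0.4, (1, 1): 0.9}, {})
        sol = tracking.solve(cg)
        assert (0, 1) not in sol.nodes
        assert (1, 1) in sol.nodes  # positive score, no disappear cost at end

    def test_empty_graph_rejected(self):
        cg = manual_graph({}, {})
        with pytest.raises(ValueError):
            tracking.solve(cg)

    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cg = tracking.random_candidate_graph(rng)
            sol = tracking.solve(cg)
            tracking.audit_solution(sol)
            oracle = tracking.brute_force_solve(cg)
            assert sol.objective == pytest.approx(oracle.objective, abs=1e-9)

    def test_raising_appear_cost_never_adds_appearances(self):
        rng = np.random.default_rng(7)
        cg = tracking.random_candidate_graph(rng)
        counts = []
        for cost in (0.0, 0.4, 0.8, 1.6, 3.2):
            cg.params.appear_cost = cost
            counts.append(len(tracking.solve(cg).appearances))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFusionExtraction:
    def test_scheduled_fusions_recovered(self, fusion_scene):
        sol = tracking.track_lumens(
            fusion_scene.gt_lumen_instances, fusion_scene.spacing
        )
        tracking.audit_solution(sol)
        table, counts, hours = tracking.extract_fusions(
            sol, fusion_scene.params.frame_interval
        )
        assert len(table) == 3
        scheduled = sorted(f for f, _, _ in fusion_scene.gt_fusions)
        detected = sorted(table.frame)
        assert all(abs(a - b) <= 1 for a, b in zip(detected, scheduled))
        # smoothed counts: rolling mean of an impulse within window 10
        impulse_frames = counts[counts.fusions > 0].frame
        assert len(impulse_frames) == 3
        # hours-since-fusion: the fusion node itself is at distance 0
        for n in sol.fusions:
            assert hours[n] == 0.0

    def test_no_fusions_empty_outputs(self):
        cg = manual_graph(
            {(0, 1): 0.5, (1, 1): 0.5},
            {((0, 1), (1, 1)): 0.9},
        )
        sol = tracking.solve(cg)
        table, counts, hours = tracking.extract_fusions(sol, 1.0)
        assert table.empty
        assert counts.fusions.sum() == 0

    def test_rolling_mean_of_impulse(self):
        impulse = pd.Series([0] * 12)
        impulse.iloc[5] = 1
        smoothed = impulse.rolling(10, min_periods=1).mean()
        assert smoothed.iloc[9] == pytest.approx(0.1)


class TestTracklets:
    def test_purity_on_synthetic_cells(self, tracking_scene):
        sol = tracking.build_tracklets(
            tracking_scene.gt_cell_instances, tracking_scene.spacing
        )
        tracking.audit_solution(sol)
        same = sum(1 for (u, v) in sol.edges if u[1] == v[1])
        assert same / len(sol.edges) >= 0.95

    def test_single_frame_movie_all_nodes_no_edges(self, tracking_scene):
        sol = tracking.build_tracklets(
            tracking_scene.gt_cell_instances[:1], tracking_scene.spacing
        )
        assert len(sol.nodes) > 0
        assert not sol.edges

    def test_crossing_cells_do_not_swap(self):
        # two spheres pass each other with lanes > 24.3 um apart
        nt, sz = 5, 64
        movie = np.zeros((nt, 24, 64, 90), dtype=np.uint16)
        for t in range(nt):
            m1 = _ball_mask((24, 64, 90), (1, 1, 1),
                            np.array([12.0, 18.0, 15.0 + 12 * t]), 8.0)
            m2 = _ball_mask((24, 64, 90), (1, 1, 1),
                            np.array([12.0, 46.0, 75.0 - 12 * t]), 8.0)
            movie[t][m1] = 1
            movie[t][m2] = 2
        params = tracking.cell_params(max_dist_um=24.3,
                                      min_mask_vol_um3=1444.0,
                                      min_vol_um3=481.6)
        sol = tracking.build_tracklets(movie, (1, 1, 1), params)
        for u, v in sol.edges:
            assert u[1] == v[1]

    def test_tracklet_caps_enforced(self):
        params = tracking.cell_params()
        params.max_children = 2
        with pytest.raises(ValueError):
            tracking.build_tracklets(
                np.zeros((2, 4, 4, 4), dtype=np.uint16), (1, 1, 1), params
            )
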