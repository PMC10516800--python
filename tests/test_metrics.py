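"""Connectivity density, degrees, hubs, degree changes and layout."""

import itertools

import numpy as np
import pytest

from metaconn.connectivity import Edge, EdgeSet
from metaconn.metrics import (build_graph, connectivity_density, degree_change,
                              density_table, identify_hubs, layout,
                              node_degrees)

from .conftest import make_small_registry


def edge_set(pairs_with_sign, alpha=0.05, provenance="within_group"):
    edges = tuple(Edge(i, j, s, 0.5 * s) for i, j, s in pairs_with_sign)
    return EdgeSet(edges, provenance, alpha)


def first_pairs(registry, structure_a, structure_b, count):
    """Deterministic list of the first `count` ROI pairs for a structure pair."""
    a_ids = [r.roi_id for r in registry.rois_in(structure_a)]
    if structure_a == structure_b:
        pairs = itertools.combinations(a_ids, 2)
    else:
        b_ids = [r.roi_id for r in registry.rois_in(structure_b)]
        pairs = itertools.product(a_ids, b_ids)
    return list(itertools.islice(pairs, count))


class TestConnectivityDensity:
    def test_worked_examples_on_default_registry(self, registry176):
        # 151 positive within-CP edges -> 151/2145 = 7.04%;
        # 10 positive CP-TH edges -> 10/1386 = 0.72%
        pairs = first_pairs(registry176, "CP", "CP", 151)
        pairs += first_pairs(registry176, "CP", "TH", 10)
        edges = edge_set([(i, j, +1) for i, j in pairs])
        assert connectivity_density(edges, registry176, "CP", "CP", +1) == pytest.approx(7.04, abs=0.005)
        assert connectivity_density(edges, registry176, "CP", "TH", +1) == pytest.approx(0.72, abs=0.005)
        assert connectivity_density(edges, registry176, "CP", "CP", -1) == 0.0

    def test_empty_edge_set_gives_zero_everywhere(self, registry176):
        edges = edge_set([])
        report = density_table(edges, registry176)
        assert (report["positive_density"] == 0).all()
        assert (report["negative_density"] == 0).all()

    def test_all_pairs_positive_gives_100(self):
        reg = make_small_registry({"CP": 3, "TH": 2})
        pairs = itertools.combinations(reg.roi_ids, 2)
        edges = edge_set([(i, j, +1) for i, j in pairs])
        report = density_table(edges, reg)
        assert (report["positive_density"] == 100.0).all()
        assert (report["negative_density"] == 0.0).all()

    def test_density_table_agrees_with_cellwise_density(self, registry176):
        rng = np.random.default_rng(0)
        all_pairs = list(itertools.combinations(registry176.roi_ids, 2))
        chosen = rng.choice(len(all_pairs), size=300, replace=False)
        edges = edge_set([(all_pairs[k][0], all_pairs[k][1],
                           +1 if rng.random() < 0.7 else -1) for k in chosen])
        report = density_table(edges, registry176)
        for row in report.itertuples():
            assert row.positive_density == pytest.approx(
                connectivity_density(edges, registry176, row.structure_a,
                                     row.structure_b, +1))
            assert row.negative_density == pytest.approx(
                connectivity_density(edges, registry176, row.structure_a,
                                     row.structure_b, -1))
        # counts over all structure pairs partition the edge set
        assert (report["positive_count"].sum() + report["negative_count"].sum()
                == len(edges))

    def test_structure_labels(self, registry176):
        report = density_table(edge_set([]), registry176)
        assert set(report["structure_a"]) == {"CP", "SNr", "GPe", "MOTOR", "PFC", "TH"}

    def test_undefined_density_raises(self):
        reg = make_small_registry({"CP": 1, "TH": 2})
        with pytest.raises(ValueError, match="undefined"):
            connectivity_density(edge_set([]), reg, "CP", "CP", +1)


class TestDegreesAndHubs:
    def test_triangle_and_star(self):
        reg = make_small_registry({"CP": 6})
        ids = reg.roi_ids
        triangle = build_graph(edge_set([(ids[0], ids[1], 1), (ids[1], ids[2], 1),
                                         (ids[0], ids[2], -1)]), reg)
        deg = node_degrees(triangle, reg).degrees
        assert all(deg[ids[k]] == 2 for k in range(3))
        assert all(deg[ids[k]] == 0 for k in range(3, 6))

        star = build_graph(edge_set([(ids[0], ids[k], 1) for k in range(1, 6)]), reg)
        deg = node_degrees(star, reg).degrees
        assert deg[ids[0]] == 5
        assert all(deg[ids[k]] == 1 for k in range(1, 6))

    def test_handshake_lemma_on_random_graphs(self, registry176):
        rng = np.random.default_rng(1)
        all_pairs = list(itertools.combinations(registry176.roi_ids, 2))
        for trial in range(3):
            chosen = rng.choice(len(all_pairs), size=500, replace=False)
            edges = edge_set([(all_pairs[k][0], all_pairs[k][1], 1) for k in chosen])
            graph = build_graph(edges, registry176)
            report = node_degrees(graph, registry176)
            assert report.frame["degree"].sum() == 2 * len(edges)

    def test_hub_count_is_ceil_fraction(self, registry176):
        rng = np.random.default_rng(2)
        all_pairs = list(itertools.combinations(registry176.roi_ids, 2))
        chosen = rng.choice(len(all_pairs), size=400, replace=False)
        edges = edge_set([(all_pairs[k][0], all_pairs[k][1], 1) for k in chosen])
        report = identify_hubs(node_degrees(build_graph(edges, registry176),
                                            registry176))
        assert len(report.hubs) == 18  # ceil(0.10 * 176)

    def test_tie_break_by_registry_order(self):
        reg = make_small_registry({"CP": 10})
        report = identify_hubs(node_degrees(build_graph(edge_set([]), reg), reg),
                               fraction=0.25)
        # all degrees equal (0): first ceil(0.25*10)=3 nodes in registry order
        assert report.hubs == reg.roi_ids[:3]

    def test_unique_maximum_is_the_hub(self):
        reg = make_small_registry({"CP": 10})
        ids = reg.roi_ids
        edges = edge_set([(ids[4], ids[k], 1) for k in (5, 6, 7)])
        report = identify_hubs(node_degrees(build_graph(edges, reg), reg),
                               fraction=0.10)
        assert report.hubs == [ids[4]]


class TestDegreeChange:
    def test_identical_reports_all_zero(self, registry176):
        graph = build_graph(edge_set([]), registry176)
        rep = node_degrees(graph, registry176)
        ranked = degree_change(rep, rep)
        assert (ranked["degree_delta"] == 0).all()

    def test_single_gainer_ranked_first(self):
        reg = make_small_registry({"CP": 5})
        ids = reg.roi_ids
        g1 = build_graph(edge_set([]), reg)
        g2 = build_graph(edge_set([(ids[2], ids[k], 1) for k in (0, 1, 3)]), reg)
        ranked = degree_change(node_degrees(g1, reg), node_degrees(g2, reg))
        assert ranked.iloc[0]["roi_id"] == ids[2]
        assert ranked.iloc[0]["degree_delta"] == 3

    def test_deltas_sum_to_edge_difference(self, registry176):
        rng = np.random.default_rng(3)
        all_pairs = list(itertools.combinations(registry176.roi_ids, 2))
        e1 = edge_set([(all_pairs[k][0], all_pairs[k][1], 1)
                       for k in rng.choice(len(all_pairs), 120, replace=False)])
        e2 = edge_set([(all_pairs[k][0], all_pairs[k][1], 1)
                       for k in rng.choice(len(all_pairs), 200, replace=False)])
        r1 = node_degrees(build_graph(e1, registry176), registry176)
        r2 = node_degrees(build_graph(e2, registry176), registry176)
        ranked = degree_change(r1, r2)
        assert ranked["degree_delta"].sum() == 2 * (len(e2) - len(e1))
        swapped = degree_change(r2, r1)
        merged = ranked.set_index("roi_id")["degree_delta"]
        merged_swapped = swapped.set_index("roi_id")["degree_delta"]
        assert (merged + merged_swapped == 0).all()


class TestLayout:
    def test_deterministic_for_fixed_seed(self):
        reg = make_small_registry({"CP": 8})
        ids = reg.roi_ids
        edges = edge_set([(ids[i], ids[j], 1) for i, j in
                          [(0, 1), (1, 2), (2, 0), (3, 4)]])
        graph = build_graph(edges, reg)
        pos1 = layout(graph, seed=7)
        pos2 = layout(graph, seed=7)
        for node in pos1:
            np.testing.assert_array_equal(pos1[node], pos2[node])

    def test_single_node_at_origin(self):
        reg = make_small_registry({"CP": 1})
        graph = build_graph(edge_set([]), reg)
        np.testing.assert_array_equal(layout(graph)[reg.roi_ids[0]], [0.0, 0.0])

    def test_cliques_are_spatially_separated(self):
        reg = make_small_registry({"CP": 5, "TH": 5})
        ids = reg.roi_ids
        edges = [(a, b, 1) for a, b in itertools.combinations(ids[:5], 2)]
        edges += [(a, b, 1) for a, b in itertools.combinations(ids[5:], 2)]
        edges += [(ids[0], ids[5], 1)]  # bridge keeps the graph connected
        graph = build_graph(edge_set(edges), reg)
        pos = layout(graph, seed=1)
        def mean_dist(group_a, group_b):
            return np.mean([np.linalg.norm(pos[a] - pos[b])
                            for a in group_a for b in group_b if a != b])
        intra = (mean_dist(ids[:5], ids[:5]) + mean_dist(ids[5:], ids[5:])) / 2
        inter = mean_dist(ids[:5], ids[5:])
        assert intra < inter

    def test_isolated_nodes_on_periphery(self):
        reg = make_small_registry({"CP": 6})
        ids = reg.roi_ids
        graph = build_graph(edge_set([(ids[0], ids[1], 1), (ids[1], ids[2], 1)]), reg)
        pos = layout(graph, seed=0)
        core_max = max(np.linalg.norm(pos[i]) for i in ids[:3])
        for isolated in ids[3:]:
            assert np.linalg.norm(pos[isolated]) > core_max
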