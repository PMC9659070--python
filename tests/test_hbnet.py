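"""Hydrogen-bond graph construction and betweenness centrality."""

import math

import networkx as nx
import numpy as np
import pytest

from _oracles import brute_betweenness
from fps import fixtures, hbnet


class TestCountWaters:
    def test_toy_water_count(self):
        plan = fixtures.GeometryPlan()
        for k in range(3):
            plan.add_water("A", 100 + k, (5.0 * k, 0.0, 0.0))
        plan.add("A", 1, "ALA", "CA", "C", (0.0, 20.0, 0.0))
        assert hbnet.count_waters(fixtures.synth_toy_structure(plan)) == 3

    def test_waterless_structure(self, three_residue_structure):
        assert hbnet.count_waters(three_residue_structure) == 0

    def test_per_chain_assignment_by_nearest_protein_atom(self):
        plan = fixtures.GeometryPlan()
        plan.add("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0))
        plan.add("B", 1, "ALA", "CA", "C", (30.0, 0.0, 0.0))
        plan.add_water("W", 100, (3.0, 0.0, 0.0))   # near chain A
        plan.add_water("W", 101, (27.0, 0.0, 0.0))  # near chain B
        plan.add_water("W", 102, (28.0, 1.0, 0.0))  # near chain B
        arr = fixtures.synth_toy_structure(plan)
        assert hbnet.count_waters(arr) == 3
        assert hbnet.count_waters(arr, chain="A") == 1
        assert hbnet.count_waters(arr, chain="B") == 2


class TestGraphConstruction:
    def test_waters_within_cutoff_bond(self):
        plan = fixtures.GeometryPlan()
        plan.add_water("A", 1, (0.0, 0.0, 0.0))
        plan.add_water("A", 2, (2.8, 0.0, 0.0))
        g = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan))
        assert g.number_of_edges() == 1

    def test_waters_beyond_cutoff_do_not_bond(self):
        plan = fixtures.GeometryPlan()
        plan.add_water("A", 1, (0.0, 0.0, 0.0))
        plan.add_water("A", 2, (3.6, 0.0, 0.0))
        g = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan))
        assert g.number_of_edges() == 0

    def test_planted_water_bridge(self, bridge_structure):
        """Ser-OG —2.9— HOH —3.0— Asp-OD1 gives a 2-edge path through the water."""
        g = hbnet.build_hbond_graph(bridge_structure)
        assert nx.shortest_path(g, "S1:A", "D3:A") == ["S1:A", "HOH:A:101", "D3:A"]
        assert g["S1:A"]["HOH:A:101"]["distance"] == pytest.approx(2.9, abs=0.01)
        assert g["HOH:A:101"]["D3:A"]["distance"] == pytest.approx(3.0, abs=0.01)

    def test_backbone_atoms_excluded(self, bridge_structure):
        # backbone amides are present in the fixture but must never appear
        # in edges (the water oxygen, also named "O", legitimately does)
        g = hbnet.build_hbond_graph(bridge_structure, d_max=50.0)
        for u, v, atoms in g.edges(data="atoms"):
            for node, atom in zip((u, v), atoms):
                if not node.startswith("HOH:"):
                    assert atom not in {"N", "CA", "C", "O", "CB"}

    def test_d_max_monotonicity(self, bridge_structure):
        edges = None
        for d_max in (2.0, 3.0, 3.5, 5.0, 8.0):
            g = hbnet.build_hbond_graph(bridge_structure, d_max=d_max)
            current = set(map(frozenset, g.edges))
            if edges is not None:
                assert edges <= current
            edges = current

    def test_atom_order_invariance(self):
        plan = fixtures.bridge_plan()
        g1 = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan))
        plan_rev = fixtures.GeometryPlan(atoms=list(reversed(plan.atoms)))
        g2 = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan_rev))
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_angle_criterion_applied_when_hydrogens_present(self):
        # donor O-H pointing away from the acceptor: H-D-A angle ~180 > 60
        plan = fixtures.GeometryPlan()
        plan.add_water("A", 1, (0.0, 0.0, 0.0))
        plan.add("A", 1, "HOH", "H1", "H", (-0.95, 0.0, 0.0))
        plan.add_water("A", 2, (2.8, 0.0, 0.0))
        plan.add("A", 2, "HOH", "H1", "H", (3.75, 0.0, 0.0))
        g = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan))
        assert g.number_of_edges() == 0
        # donor hydrogen along the axis: angle ~0 -> bonded
        plan2 = fixtures.GeometryPlan()
        plan2.add_water("A", 1, (0.0, 0.0, 0.0))
        plan2.add("A", 1, "HOH", "H1", "H", (0.95, 0.0, 0.0))
        plan2.add_water("A", 2, (2.8, 0.0, 0.0))
        g2 = hbnet.build_hbond_graph(fixtures.synth_toy_structure(plan2))
        assert g2.number_of_edges() == 1


class TestBetweenness:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        cbw = hbnet.betweenness_centrality(g)
        assert cbw == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self, hub_structure):
        g = hbnet.build_hbond_graph(hub_structure)
        cbw = hbnet.betweenness_centrality(g)
        assert cbw["S1:A"] == pytest.approx(math.comb(6, 2))
        assert max(cbw, key=cbw.get) == "S1:A"

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_enumeration_oracle(self, seed):
        g = nx.gnp_random_graph(8, 0.4, seed=seed)
        cbw = hbnet.betweenness_centrality(g)
        oracle = brute_betweenness({n: sorted(g.neighbors(n)) for n in g.nodes})
        for n in g.nodes:
            assert cbw[n] == pytest.approx(oracle[n], abs=1e-9)

    def test_tree_total_matches_oracle_total(self):
        g = nx.random_labeled_tree(12, seed=3)
        cbw = hbnet.betweenness_centrality(g)
        oracle = brute_betweenness({n: sorted(g.neighbors(n)) for n in g.nodes})
        assert sum(cbw.values()) == pytest.approx(sum(oracle.values()))

    def test_water_bridge_contraction(self, bridge_structure):
        """Contracting degree-2 waters yields the direct residue-residue links."""
        g = hbnet.build_hbond_graph(bridge_structure)
        contracted = set()
        for node in [n for n, k in g.nodes(data="kind") if k == "water"]:
            nbrs = list(g.neighbors(node))
            if len(nbrs) == 2:
                contracted.add(frozenset(nbrs))
        assert contracted == {frozenset({"S1:A", "D3:A"})}


class TestGroupStats:
    def test_uniform_centrality_ratio_one(self):
        profile = {"a": 5.0, "b": 5.0, "c": 5.0, "d": 5.0}
        groups = {"a": "low", "b": "normal", "c": "not_detected", "d": "not_detected"}
        stats = hbnet.group_centrality_stats(profile, groups)
        assert stats.ratio == pytest.approx(1.0)
        assert stats.means["low"] == (5.0, 0.0)

    def test_ratio_arithmetic(self):
        profile = {"a": 4.0, "b": 6.0, "c": 1.0, "d": 3.0}
        groups = {"a": "low", "b": "normal", "c": "not_detected", "d": "not_detected"}
        stats = hbnet.group_centrality_stats(profile, groups)
        assert stats.ratio == pytest.approx(5.0 / 2.0)

    def test_empty_group_undefined_not_zero(self):
        stats = hbnet.group_centrality_stats({"a": 1.0}, {"a": "low"})
        assert math.isnan(stats.means.get("not_detected", (math.nan, math.nan))[0]) or \
            "not_detected" not in stats.means
        assert math.isnan(stats.ratio)

    def test_detected_residues_on_hub_give_ratio_above_one(self):
        """Detected nodes planted at the path center outrank peripheral ones."""
        g = nx.path_graph(["A", "B", "C", "D", "E"])
        profile = hbnet.betweenness_centrality(g)
        stats = hbnet.group_centrality_stats(
            profile, {"C": "low", "D": "normal", "B": "not_detected"}
        )
        assert stats.ratio > 1.0

    def test_merged_ratio(self):
        s1 = hbnet.group_centrality_stats(
            {"a": 4.0, "b": 2.0}, {"a": "low", "b": "not_detected"})
        s2 = hbnet.group_centrality_stats(
            {"a": 6.0, "b": 2.0}, {"a": "low", "b": "not_detected"})
        mean, sd = hbnet.merged_network_ratio([s1, s2])
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.std([2.0, 3.0], ddof=1))
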