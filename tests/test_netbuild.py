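import numpy as np
import pytest

from commscope.netbuild import (build_graph, condensation_seeds,
                                intersect_seeds, seeds_to_frame, write_graphml)

from conftest import make_universe
from oracles import brute_force_seed_compounds


class TestBuildGraph:
    def test_substrate_product_pair_expansion(self):
        uni = make_universe([("R1", ["e1"], ["A", "B"], ["C"], False)])
        g = build_graph(uni, {"e1"})
        assert set(g.edges) == {("A", "C"), ("B", "C")}

    def test_reversible_reaction_adds_both_directions(self):
        uni = make_universe([("R2", ["e2"], ["C"], ["D"], True)])
        g = build_graph(uni, {"e2"})
        assert set(g.edges) == {("C", "D"), ("D", "C")}

    def test_two_ecs_on_one_reaction_give_no_duplicate_edges(self):
        uni = make_universe([("R1", ["e1", "e2"], ["A"], ["B"], False)])
        g1 = build_graph(uni, {"e1"})
        g2 = build_graph(uni, {"e1", "e2"})
        assert set(g1.edges) == set(g2.edges) == {("A", "B")}

    def test_empty_ec_set_gives_empty_graph(self, toy_universe):
        assert build_graph(toy_universe, set()).number_of_nodes() == 0


class TestCondensationSeeds:
    def test_chain_has_unique_source(self):
        uni = make_universe([("R1", ["e1"], ["A"], ["B"], False),
                             ("R2", ["e2"], ["B"], ["C"], False)])
        ss = condensation_seeds(build_graph(uni, None))
        assert ss.seeds == {"A"} and ss.confidence["A"] == 1.0

    def test_source_cycle_members_share_confidence(self):
        uni = make_universe([("R1", ["e1"], ["A"], ["B"], True),
                             ("R2", ["e2"], ["B"], ["C"], False)])
        ss = condensation_seeds(build_graph(uni, None))
        assert ss.seeds == {"A", "B"}
        assert ss.confidence == {"A": 0.5, "B": 0.5}

    def test_self_loop_only_node_is_a_seed(self):
        uni = make_universe([("R1", ["e1"], ["A"], ["A"], False)])
        ss = condensation_seeds(build_graph(uni, None))
        assert ss.seeds == {"A"}

    @pytest.mark.parametrize("seed", range(12))
    def test_random_digraphs_match_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        density = rng.uniform(0.05, 0.3)
        nodes = [f"C{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(n)
            if i != j and rng.random() < density
        ]
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        assert condensation_seeds(g).seeds == brute_force_seed_compounds(nodes, edges)

    def test_seeds_invariant_to_insertion_order(self):
        import networkx as nx
        rng = np.random.default_rng(3)
        edges = [(f"C{int(a)}", f"C{int(b)}")
                 for a, b in rng.integers(0, 15, size=(40, 2)) if a != b]
        g1, g2 = nx.DiGraph(), nx.DiGraph()
        g1.add_edges_from(edges)
        g2.add_edges_from(edges[::-1])
        assert condensation_seeds(g1).seeds == condensation_seeds(g2).seeds

    def test_non_seeds_are_reachable_from_a_source_component(self, default_synth):
        import networkx as nx
        _, universe, _, _, _ = default_synth
        g = build_graph(universe, None)
        ss = condensation_seeds(g)
        reachable = set(ss.seeds)
        for s in ss.seeds:
            reachable |= nx.descendants(g, s)
        assert reachable == set(g.nodes)


class TestIntersectSeeds:
    def _seedset(self, seeds, stage="raw", treatment="SM"):
        from commscope.netbuild import SeedSet
        return SeedSet(treatment=treatment,
                       confidence={s: 1.0 for s in seeds}, stage=stage)

    def test_plain_intersection_keeps_sub_confidence(self):
        out = intersect_seeds(self._seedset({"A", "X"}), self._seedset({"A", "B"}))
        assert out.seeds == {"A"} and out.stage == "intersected"

    def test_identical_sets_unchanged(self):
        out = intersect_seeds(self._seedset({"A", "B"}), self._seedset({"A", "B"}))
        assert out.seeds == {"A", "B"}

    def test_disjoint_sets_give_empty_result(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="commscope.netbuild"):
            out = intersect_seeds(self._seedset({"A"}), self._seedset({"B"}))
        assert out.seeds == set()
        assert any("empty" in r.message for r in caplog.records)

    def test_intersected_stage_cannot_be_reintersected(self):
        inter = intersect_seeds(self._seedset({"A"}), self._seedset({"A"}))
        with pytest.raises(ValueError, match="raw"):
            intersect_seeds(inter, self._seedset({"A"}))


def test_graphml_and_seed_table_exports(tmp_path, toy_universe):
    import networkx as nx
    g = build_graph(toy_universe, None)
    out = tmp_path / "g.graphml"
    write_graphml(g, out)
    back = nx.read_graphml(out)
    assert set(back.nodes) == set(g.nodes)
    df = seeds_to_frame(condensation_seeds(g, treatment="SM"))
    assert list(df.columns) == ["compound_id", "confidence", "component_id",
                                "stage", "treatment"]
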