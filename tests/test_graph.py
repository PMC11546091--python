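"""Knowledge-graph container, CSV I/O, projection and filtering."""

import numpy as np
import pandas as pd
import pytest

from kgppi.graph import (
    CooccurrenceTable,
    GraphIntegrityError,
    GraphParseError,
    KnowledgeGraph,
    Node,
    canonical_pair,
    cooccurrence_feature,
    filter_short_names,
    load_graph,
    project_unipartite,
    save_graph,
)

from conftest import random_graph


def _tables(node_rows, edge_rows):
    return (pd.DataFrame(node_rows, columns=["id", "name", "type"]),
            pd.DataFrame(edge_rows, columns=["u", "v", "type"]))


class TestLoadGraph:
    def test_minimal_two_nodes_one_edge(self):
        kg = load_graph(*_tables(
            [("a", "alpha", "protein"), ("b", "betaX", "protein")],
            [("a", "b", "binds")]))
        assert kg.n_nodes == 2 and kg.n_edges == 1
        assert kg.has_edge("b", "a")

    def test_symmetric_duplicates_merge_to_one_canonical_edge(self):
        kg = load_graph(*_tables(
            [("a", "alpha", "protein"), ("b", "betaX", "protein")],
            [("a", "b", "binds"), ("b", "a", "binds"), ("b", "a", "regulates")]))
        assert kg.n_edges == 1
        edge = kg.edges[("a", "b")]
        assert edge.types == frozenset({"binds", "regulates"})

    def test_type_census_matches_independent_row_scan(self):
        rng = np.random.default_rng(7)
        types = [f"type{i:02d}" for i in range(11)]
        rows = [(f"n{i}", f"name{i}", types[int(rng.integers(11))])
                for i in range(300)]
        kg = load_graph(*_tables(rows, []))
        expected = {}
        for _, _, t in rows:  # brute-force recount straight off the rows
            expected[t] = expected.get(t, 0) + 1
        assert kg.type_census() == expected
        assert len(kg.entity_types()) == 11

    def test_unknown_endpoint_is_referential_integrity_error(self):
        with pytest.raises(GraphIntegrityError, match="ghost"):
            load_graph(*_tables([("a", "alpha", "protein")], [("a", "ghost", "x")]))

    def test_malformed_row_error_names_row_number(self):
        nodes = pd.DataFrame([("a", "alpha", "protein", "0.5"),
                              ("b", "betaX", "protein", "not-a-number")],
                             columns=["id", "name", "type", "feat_0"])
        with pytest.raises(GraphParseError, match="row 1"):
            load_graph(nodes, pd.DataFrame(columns=["u", "v", "type"]))

    def test_self_loop_rejected(self):
        with pytest.raises(GraphParseError, match="self-loop"):
            load_graph(*_tables([("a", "alpha", "protein")], [("a", "a", "x")]))

    def test_duplicate_node_id_rejected(self):
        with pytest.raises(GraphParseError, match="duplicate"):
            load_graph(*_tables(
                [("a", "alpha", "protein"), ("a", "other", "disease")], []))


class TestProjection:
    def test_protein_triangle_with_attached_disease(self):
        kg = load_graph(*_tables(
            [("p1", "prot1", "protein"), ("p2", "prot2", "protein"),
             ("p3", "prot3", "protein"), ("d1", "illness", "disease")],
            [("p1", "p2", "i"), ("p2", "p3", "i"), ("p1", "p3", "i"),
             ("d1", "p1", "a"), ("d1", "p2", "a"), ("d1", "p3", "a")]))
        proj = project_unipartite(kg, "protein")
        assert sorted(proj.nodes) == ["p1", "p2", "p3"]
        assert proj.n_edges == 3

    def test_no_intra_type_edges_gives_edgeless_projection(self):
        kg = load_graph(*_tables(
            [("p1", "prot1", "protein"), ("d1", "illness", "disease")],
            [("d1", "p1", "a")]))
        proj = project_unipartite(kg, "protein")
        assert proj.n_nodes == 1 and proj.n_edges == 0

    def test_absent_type_warns_and_returns_empty(self, caplog):
        kg = random_graph(10, 5, seed=1)
        with caplog.at_level("WARNING"):
            proj = project_unipartite(kg, "no-such-type")
        assert proj.n_nodes == 0 and proj.n_edges == 0
        assert any("no-such-type" in r.message for r in caplog.records)

    def test_matches_bruteforce_endpoint_filter_on_random_graph(self):
        rng = np.random.default_rng(3)
        kg = KnowledgeGraph()
        types = ["protein", "disease", "drug"]
        names = [f"N{i:03d}x" for i in range(40)]
        for name in names:
            kg.add_node(Node(name, name, types[int(rng.integers(3))]))
        from itertools import combinations
        pairs = list(combinations(names, 2))
        for i in rng.choice(len(pairs), size=120, replace=False):
            kg.add_edge(*pairs[i])
        proj = project_unipartite(kg, "protein")
        expected = {
            pair for pair in kg.edges
            if kg.nodes[pair[0]].entity_type == "protein"
            and kg.nodes[pair[1]].entity_type == "protein"
        }
        assert set(proj.edges) == expected

    def test_projection_is_idempotent(self):
        kg = random_graph(30, 60, seed=5)
        once = project_unipartite(kg, "protein")
        twice = project_unipartite(once, "protein")
        assert set(twice.nodes) == set(once.nodes)
        assert set(twice.edges) == set(once.edges)


class TestFilterShortNames:
    def test_four_character_name_removed_five_kept(self):
        kg = KnowledgeGraph()
        kg.add_node(Node("a", "ABCD", "protein"))    # 4 chars: removed
        kg.add_node(Node("b", "ABCDE", "protein"))   # 5 chars: kept
        kg.add_edge("a", "b")
        out = filter_short_names(kg, min_chars=5)
        assert sorted(out.nodes) == ["b"]
        assert out.n_edges == 0

    def test_survivors_match_bruteforce_length_scan(self):
        rng = np.random.default_rng(11)
        kg = KnowledgeGraph()
        for i in range(50):
            name = "X" * int(rng.integers(1, 10))
            kg.add_node(Node(f"n{i}", name, "protein"))
        out = filter_short_names(kg, min_chars=5)
        expected = {nid for nid, n in kg.nodes.items() if len(n.name) >= 5}
        assert set(out.nodes) == expected

    def test_filter_and_projection_commute(self):
        kg = random_graph(25, 40, seed=9)
        # give some nodes short names and mixed types
        rng = np.random.default_rng(2)
        for nid in list(kg.nodes):
            node = kg.nodes[nid]
            name = node.name[: int(rng.integers(2, 9))]
            etype = "disease" if rng.random() < 0.3 else "protein"
            kg.nodes[nid] = Node(nid, name, etype)
        a = project_unipartite(filter_short_names(kg, 5), "protein")
        b = filter_short_names(project_unipartite(kg, "protein"), 5)
        assert set(a.nodes) == set(b.nodes)
        assert set(a.edges) == set(b.edges)

    def test_min_chars_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_short_names(KnowledgeGraph(), min_chars=0)


class TestCooccurrence:
    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.0, 1.0), (0.05, 0.95)])
    def test_feature_is_one_minus_p(self, p, expected):
        assert cooccurrence_feature(p) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValueError):
            cooccurrence_feature(p)

    def test_table_canonicalizes_and_distinguishes_missing(self, tmp_path):
        table = CooccurrenceTable()
        table.set("zeta", "alpha", 0.2)
        assert table.get("alpha", "zeta") == pytest.approx(0.2)
        assert table.feature("zeta", "alpha") == pytest.approx(0.8)
        assert table.get("alpha", "other") is None
        assert table.feature("alpha", "other") is None
        path = tmp_path / "cooc.csv"
        table.to_csv(path)
        again = CooccurrenceTable.from_csv(path)
        assert dict(again.items()) == dict(table.items())

    def test_table_rejects_bad_p(self):
        with pytest.raises(ValueError):
            CooccurrenceTable({("a", "b"): 1.5})


class TestRoundTrip:
    def test_save_load_save_is_bit_identical(self, tmp_path, small_world):
        kg = small_world.kg
        n1, e1 = tmp_path / "n1.csv", tmp_path / "e1.csv"
        save_graph(kg, n1, e1)
        kg2 = load_graph(n1, e1)
        n2, e2 = tmp_path / "n2.csv", tmp_path / "e2.csv"
        save_graph(kg2, n2, e2)
        assert n1.read_bytes() == n2.read_bytes()
        assert e1.read_bytes() == e2.read_bytes()
        assert set(kg2.edges) == set(kg.edges)
        assert all(kg2.nodes[n].features == kg.nodes[n].features for n in kg.nodes)


def test_canonical_pair_orders_and_rejects_self():
    assert canonical_pair("b", "a") == ("a", "b")
    with pytest.raises(ValueError):
        canonical_pair("a", "a")
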