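"""Non-edge enumeration, co-occurrence filtering and the discovery cascade."""

from itertools import combinations

import numpy as np
import pytest

import kgppi
from kgppi import CooccurrenceTable, KnowledgeGraph, MlpConfig, Node
from kgppi.discovery import (
    DiscoveryAudit,
    ExpandedNetwork,
    NewEdge,
    _interaction_nature,
    enumerate_nonedges,
    filter_by_cooccurrence,
    run_discovery,
)
from kgppi.docstore import InMemoryDocumentStore
from kgppi.gnn import EmbeddingTable
from kgppi.mlp import MlpModel
from kgppi.validator import ValidatorVerdict, mock_backend

from conftest import random_graph


class TestCooccurrenceFilter:
    def _store(self, pvalues):
        store = InMemoryDocumentStore()
        for obj, p in pvalues.items():
            store.set_object_pvalue(obj, "query", p)
        return store

    def test_threshold_boundaries(self):
        store = self._store({"keep1": 0.04, "edge1": 0.05, "drop1": 0.06})
        kept = filter_by_cooccurrence(["keep1", "edge1", "drop1"], "query", store)
        assert kept == ["keep1", "edge1"]  # p = alpha is kept; only p > alpha drops

    def test_missing_pvalue_drops_with_warning(self, caplog):
        store = self._store({"known": 0.01})
        with caplog.at_level("WARNING"):
            kept = filter_by_cooccurrence(["known", "mystery"], "query", store)
        assert kept == ["known"]
        assert any("mystery" in r.message for r in caplog.records)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        pvalues = {f"obj{i}": float(rng.random()) for i in range(100)}
        store = self._store(pvalues)
        kept = filter_by_cooccurrence(sorted(pvalues), "query", store, alpha=0.05)
        assert kept == [o for o in sorted(pvalues) if pvalues[o] <= 0.05]


class TestEnumerateNonedges:
    def test_complete_subgraph_has_none(self):
        kg = KnowledgeGraph()
        for name in ("aaaaa", "bbbbb", "ccccc"):
            kg.add_node(Node(name, name, "protein"))
        for u, v in combinations(("aaaaa", "bbbbb", "ccccc"), 2):
            kg.add_edge(u, v)
        assert enumerate_nonedges(kg) == []

    def test_five_isolated_nodes_give_ten_pairs(self):
        kg = KnowledgeGraph()
        for i in range(5):
            kg.add_node(Node(f"n{i}xxx", f"n{i}xxx", "protein"))
        assert len(enumerate_nonedges(kg)) == 10

    def test_count_matches_complement_on_random_graph(self):
        kg = random_graph(30, 80, seed=3)
        pairs = enumerate_nonedges(kg)
        assert len(pairs) == 30 * 29 // 2 - 80
        assert not (set(pairs) & set(kg.edges))

    def test_unknown_subset_node_rejected(self):
        kg = random_graph(5, 3, seed=0)
        with pytest.raises(ValueError):
            enumerate_nonedges(kg, nodes=["missing"])


class TestInteractionNature:
    @pytest.mark.parametrize("text,expected", [
        ("the context states A binds B", "physical binding"),
        ("A regulates transcription of B", "regulatory"),
        ("the proteins co-localize at the membrane", "co-localization"),
        ("an association was reported", "untyped"),
    ])
    def test_keyword_map(self, text, expected):
        assert _interaction_nature([text]) == expected


def _constant_model(prob_logit: float, in_dim: int = 129) -> MlpModel:
    """MLP whose output is a constant logit, for plumbing tests."""
    model = MlpModel(in_dim, MlpConfig())
    model.initialize(np.random.default_rng(0))
    for key in model.params:
        model.params[key][:] = 0.0
    model.params[f"b{model.n_layers - 1}"][:] = prob_logit
    return model


class TestRunDiscovery:
    def _tiny_world(self):
        kg = KnowledgeGraph()
        names = ["PROTA", "PROTB", "PROTC", "PROTD"]
        for name in names:
            kg.add_node(Node(name, name, "protein"))
        kg.add_edge("PROTA", "PROTB")
        rng = np.random.default_rng(0)
        emb = EmbeddingTable({n: rng.standard_normal(64) for n in names})
        cooc = CooccurrenceTable()
        for u, v in combinations(names, 2):
            cooc.set(u, v, 0.01)
        store = InMemoryDocumentStore()
        store.add_document("PROTA", "PROTC", "docY", "PROTA binds PROTC in cells.")
        store.add_document("PROTB", "PROTD", "docN",
                           "PROTB was assayed. PROTD was assayed separately.")
        return kg, emb, cooc, store

    def test_planted_edge_recovered_and_decoy_rejected(self):
        kg, emb, cooc, store = self._tiny_world()
        model = _constant_model(prob_logit=2.0)  # classify everything positive
        network = run_discovery(kg, cooc, store, emb, model, mock_backend)
        found = {e.pair for e in network.new_edges}
        assert found == {("PROTA", "PROTC")}
        assert network.new_edges[0].nature == "physical binding"
        # positives without documents are reported unverified, never added
        assert ("PROTA", "PROTD") in network.audit.unverified

    def test_empty_candidate_set_returns_input_unchanged(self):
        kg = KnowledgeGraph()
        for name in ("PROTA", "PROTB"):
            kg.add_node(Node(name, name, "protein"))
        kg.add_edge("PROTA", "PROTB")
        emb = EmbeddingTable({n: np.zeros(64) for n in kg.nodes})
        network = run_discovery(kg, CooccurrenceTable(), InMemoryDocumentStore(),
                                emb, _constant_model(2.0), mock_backend)
        assert network.new_edges == [] and network.audit.candidates == 0

    def test_pairs_absent_from_cooccurrence_are_skipped(self):
        kg, emb, cooc, store = self._tiny_world()
        sparse = CooccurrenceTable({("PROTA", "PROTC"): 0.01})
        network = run_discovery(kg, sparse, store, emb,
                                _constant_model(2.0), mock_backend)
        assert network.audit.candidates == 5
        assert network.audit.with_features == 1

    def test_audit_counts_are_monotonically_nonincreasing(self, discovery_network):
        audit = discovery_network.audit
        assert (audit.candidates >= audit.with_features
                >= audit.classified_positive >= audit.with_documents
                >= audit.confirmed)

    def test_rerun_reproduces_network_exactly(self, default_world, protein_graph,
                                              gnn_result, trained_mlp,
                                              discovery_network):
        again = run_discovery(protein_graph, default_world.cooc,
                              default_world.store, gnn_result.embeddings,
                              trained_mlp, mock_backend)
        assert [e.pair for e in again.new_edges] == \
            [e.pair for e in discovery_network.new_edges]
        assert again.audit.as_dict() == discovery_network.audit.as_dict()

    def test_new_edges_disjoint_from_base_and_all_confirmed(self, discovery_network):
        for edge in discovery_network.new_edges:
            assert edge.pair not in discovery_network.base.edges
            assert any(v.is_yes for v in edge.verdicts)


class TestExpandedNetworkInvariants:
    def test_edge_already_in_base_rejected(self):
        kg = KnowledgeGraph()
        for name in ("PROTA", "PROTB"):
            kg.add_node(Node(name, name, "protein"))
        kg.add_edge("PROTA", "PROTB")
        yes = ValidatorVerdict(decision="YES")
        bad = NewEdge(("PROTA", "PROTB"), 0.9, ("d",), (yes,), "untyped")
        with pytest.raises(ValueError, match="already in the base graph"):
            ExpandedNetwork(kg, [bad], DiscoveryAudit())

    def test_edge_without_yes_verdict_rejected(self):
        kg = KnowledgeGraph()
        for name in ("PROTA", "PROTB"):
            kg.add_node(Node(name, name, "protein"))
        no = ValidatorVerdict(decision="NO")
        bad = NewEdge(("PROTA", "PROTB"), 0.9, ("d",), (no,), "untyped")
        with pytest.raises(ValueError, match="YES verdict"):
            ExpandedNetwork(kg, [bad], DiscoveryAudit())

    def test_serialization(self, tmp_path, discovery_network):
        discovery_network.to_json(tmp_path / "net.json")
        discovery_network.edges_to_csv(tmp_path / "edges.csv")
        import json
        payload = json.loads((tmp_path / "net.json").read_text())
        assert len(payload["new_edges"]) == len(discovery_network.new_edges)
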