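"""Shared fixtures: synthetic worlds and trained models.

Expensive artifacts (the default world, the trained GNN and MLP, the
discovery run) are session-scoped so the recovery, ablation and
integration tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import kgppi
from kgppi import GnnConfig, MlpConfig, WorldConfig


@pytest.fixture(scope="session")
def default_world():
    return kgppi.make_world(WorldConfig())


@pytest.fixture(scope="session")
def small_world():
    return kgppi.make_world(WorldConfig(
        n_proteins=60, n_other_entities=8, n_blocks=3, n_heldout=5,
        n_decoys=5, seed=0))


@pytest.fixture(scope="session")
def protein_graph(default_world):
    return kgppi.project_unipartite(default_world.kg, "protein")


@pytest.fixture(scope="session")
def gnn_result(protein_graph):
    return kgppi.train_gnn(protein_graph, GnnConfig(seed=0))


@pytest.fixture(scope="session")
def trained_mlp(default_world, gnn_result):
    X, y, _ = kgppi.pair_training_data(default_world, gnn_result.embeddings)
    return kgppi.train_mlp(X, y, MlpConfig(seed=0))


@pytest.fixture(scope="session")
def discovery_network(default_world, protein_graph, gnn_result, trained_mlp):
    return kgppi.run_discovery(
        protein_graph, default_world.cooc, default_world.store,
        gnn_result.embeddings, trained_mlp, kgppi.mock_backend)


def random_graph(n_nodes: int, n_edges: int, seed: int = 0,
                 entity_type: str = "protein") -> kgppi.KnowledgeGraph:
    """Seeded random graph helper used by several test modules."""
    from itertools import combinations

    rng = np.random.default_rng(seed)
    kg = kgppi.KnowledgeGraph()
    names = [f"NODE{i:04d}" for i in range(n_nodes)]
    for name in names:
        kg.add_node(kgppi.Node(name, name, entity_type))
    pairs = list(combinations(names, 2))
    for i in rng.choice(len(pairs), size=n_edges, replace=False):
        kg.add_edge(*pairs[i], {"assoc"})
    return kg
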