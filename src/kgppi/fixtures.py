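"""Seeded synthetic worlds with planted structure for every pipeline stage.

A world is a planted-partition protein graph (high within-block, low
between-block edge probability) embedded in a small heterogeneous graph,
plus the signals the downstream stages consume:

* a co-occurrence table in which truly interacting pairs draw small
  p-values (Beta skewed toward 0) and null pairs draw uniform p-values;
* a templated abstract corpus in which every true and planted-missing
  pair is linked by an interaction verb inside one sentence, while decoy
  pairs are only co-mentioned in separate sentences;
* ground truth: the held-out (planted-missing) pairs a discovery run
  should recover and the decoy pairs it should reject.

The verb lexicon is shared with the mock validation backend, so the
text-validation stage is decidable without a language model. Everything
is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .docstore import InMemoryDocumentStore
from .gnn import ConfigurationError, EmbeddingTable
from .graph import CooccurrenceTable, KnowledgeGraph, Node, canonical_pair, save_graph
from .mlp import build_pair_feature
from .validator import INTERACTION_VERBS

__all__ = [
    "WorldConfig",
    "WorldTruth",
    "World",
    "make_world",
    "world_report",
    "pair_training_data",
    "make_classifier_fixture",
]

Pair = tuple[str, str]

_OTHER_TYPES = ("disease", "drug", "metabolite", "pathway")
_POSITIVE_TEMPLATE = (
    "{a} {verb} {b} in human cells. The association was observed consistently "
    "across independent assays."
)
_DECOY_TEMPLATE = (
    "Expression of {a} was quantified in patient samples. Levels of {b} were "
    "also measured in the same cohort. No functional relationship was assessed."
)
QUERY_TERM = "sleeplessness"


@dataclass(frozen=True)
class WorldConfig:
    n_proteins: int = 200
    n_other_entities: int = 20
    n_blocks: int = 4
    p_within: float = 0.3
    p_between: float = 0.01
    p_alpha: float = 1.0  # Beta parameters for true-pair co-occurrence p
    p_beta: float = 19.0
    n_heldout: int = 20
    n_decoys: int = 20
    n_null_cooc: int | None = None  # default: one null pair per true pair
    n_features: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_alpha <= 0 or self.p_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_blocks < 1 or self.n_proteins < self.n_blocks:
            raise ValueError("need at least one protein per block")


@dataclass(frozen=True)
class WorldTruth:
    true_pairs: frozenset[Pair]
    heldout_pairs: frozenset[Pair]
    decoy_pairs: frozenset[Pair]


@dataclass
class World:
    config: WorldConfig
    kg: KnowledgeGraph
    cooc: CooccurrenceTable
    store: InMemoryDocumentStore
    truth: WorldTruth
    null_pairs: list[Pair] = field(default_factory=list)
    documents: list[dict] = field(default_factory=list)

    def canonical_dict(self) -> dict:
        """Fully ordered plain representation, for determinism checks and export."""
        return {
            "nodes": [
                {"id": n.node_id, "name": n.name, "type": n.entity_type,
                 "features": [repr(x) for x in n.features]}
                for _, n in sorted(self.kg.nodes.items())
            ],
            "edges": [
                {"u": e.u, "v": e.v, "types": sorted(e.types)}
                for _, e in sorted(self.kg.edges.items())
            ],
            "cooc": [[u, v, repr(p)] for (u, v), p in sorted(self.cooc.items())],
            "documents": self.documents,
            "truth": {
                "true_pairs": sorted(map(list, self.truth.true_pairs)),
                "heldout_pairs": sorted(map(list, self.truth.heldout_pairs)),
                "decoy_pairs": sorted(map(list, self.truth.decoy_pairs)),
            },
            "null_pairs": sorted(map(list, self.null_pairs)),
        }

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_graph(self.kg, out / "nodes.csv", out / "edges.csv")
        self.cooc.to_csv(out / "cooc.csv")
        with open(out / "docs.jsonl", "w") as fh:
            for doc in self.documents:
                fh.write(json.dumps(doc, sort_keys=True) + "\n")
        (out / "truth.json").write_text(json.dumps(
            self.canonical_dict()["truth"], indent=1, sort_keys=True))


def _protein_name(i: int) -> str:
    return f"PROT{i:04d}"


def make_world(cfg: WorldConfig = WorldConfig()) -> World:
    """Generate a world; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    # --- nodes ------------------------------------------------------------
    kg = KnowledgeGraph()
    proteins = [_protein_name(i) for i in range(cfg.n_proteins)]
    block_of = {name: i * cfg.n_blocks // cfg.n_proteins for i, name in enumerate(proteins)}
    n_total = cfg.n_proteins + cfg.n_other_entities
    features = rng.standard_normal((n_total, cfg.n_features))
    for i, name in enumerate(proteins):
        kg.add_node(Node(name, name, "protein", tuple(map(float, features[i]))))
    others = []
    for j in range(cfg.n_other_entities):
        etype = _OTHER_TYPES[j % len(_OTHER_TYPES)]
        name = f"{etype.upper()}{j:03d}"
        others.append(name)
        kg.add_node(Node(name, name, etype,
                         tuple(map(float, features[cfg.n_proteins + j]))))

    # --- planted-partition protein edges ----------------------------------
    pairs = list(combinations(proteins, 2))
    probs = np.array([
        cfg.p_within if block_of[u] == block_of[v] else cfg.p_between
        for u, v in pairs
    ])
    draws = rng.random(len(pairs))
    protein_edges = [canonical_pair(u, v) for (u, v), d, q in zip(pairs, draws, probs) if d < q]

    # --- heterogeneous attachment edges ------------------------------------
    for name in others:
        k = int(rng.integers(3, 9))
        targets = rng.choice(cfg.n_proteins, size=k, replace=False)
        for t in targets:
            kg.add_edge(name, proteins[int(t)], {"associated"})

    # --- plant held-out pairs (removed before the graph is emitted) --------
    within_edges = [e for e in protein_edges if block_of[e[0]] == block_of[e[1]]]
    if cfg.n_heldout > len(within_edges):
        raise ConfigurationError(
            f"cannot hold out {cfg.n_heldout} pairs; only {len(within_edges)} "
            f"within-block edges were realized"
        )
    heldout_idx = rng.choice(len(within_edges), size=cfg.n_heldout, replace=False)
    heldout = {within_edges[i] for i in sorted(heldout_idx)}
    kept_edges = [e for e in protein_edges if e not in heldout]
    for u, v in kept_edges:
        kg.add_edge(u, v, {"interacts"})

    # --- decoys: co-mention-only within-block non-edges ---------------------
    edge_set = set(protein_edges)
    within_nonedges = [
        canonical_pair(u, v)
        for u, v in pairs
        if block_of[u] == block_of[v] and canonical_pair(u, v) not in edge_set
    ]
    if cfg.n_decoys > len(within_nonedges):
        raise ConfigurationError("not enough within-block non-edges for decoys")
    decoy_idx = rng.choice(len(within_nonedges), size=cfg.n_decoys, replace=False)
    decoys = {within_nonedges[i] for i in sorted(decoy_idx)}

    truth = WorldTruth(
        true_pairs=frozenset(kept_edges),
        heldout_pairs=frozenset(heldout),
        decoy_pairs=frozenset(decoys),
    )

    # --- co-occurrence table -------------------------------------------------
    cooc = CooccurrenceTable()
    signal_pairs = sorted(kept_edges) + sorted(heldout) + sorted(decoys)
    for (u, v), p in zip(signal_pairs, rng.beta(cfg.p_alpha, cfg.p_beta, len(signal_pairs))):
        cooc.set(u, v, float(p))
    n_null = len(kept_edges) if cfg.n_null_cooc is None else cfg.n_null_cooc
    excluded = edge_set | decoys
    nonedges = [
        canonical_pair(u, v) for u, v in pairs if canonical_pair(u, v) not in excluded
    ]
    if n_null > len(nonedges):
        raise ConfigurationError("not enough null non-edges for the co-occurrence table")
    null_idx = rng.choice(len(nonedges), size=n_null, replace=False)
    null_pairs = [nonedges[i] for i in sorted(null_idx)]
    for (u, v), p in zip(null_pairs, rng.random(n_null)):
        cooc.set(u, v, float(p))

    # --- abstract corpus -----------------------------------------------------
    store = InMemoryDocumentStore()
    documents: list[dict] = []
    doc_counter = 0

    def add_doc(u: str, v: str, text: str, label: int) -> None:
        nonlocal doc_counter
        doc_id = f"DOC{doc_counter:06d}"
        doc_counter += 1
        store.add_document(u, v, doc_id, text)
        documents.append({"doc_id": doc_id, "u": u, "v": v, "text": text, "label": label})

    verb_draws = rng.integers(0, len(INTERACTION_VERBS), size=len(signal_pairs))
    for (u, v), vi in zip(sorted(kept_edges) + sorted(heldout), verb_draws):
        add_doc(u, v, _POSITIVE_TEMPLATE.format(a=u, verb=INTERACTION_VERBS[vi], b=v), 1)
    for u, v in sorted(decoys):
        add_doc(u, v, _DECOY_TEMPLATE.format(a=u, b=v), 0)

    # object-level significance against the world's query term
    for name, p in zip(proteins, rng.random(cfg.n_proteins)):
        store.set_object_pvalue(name, QUERY_TERM, float(p))

    return World(config=cfg, kg=kg, cooc=cooc, store=store, truth=truth,
                 null_pairs=null_pairs, documents=documents)


def world_report(world: World) -> dict:
    """Summary statistics recomputed from the world's containers."""
    def mean_p(pairs) -> float | None:
        ps = [world.cooc.get(u, v) for u, v in pairs]
        ps = [p for p in ps if p is not None]
        return float(np.mean(ps)) if ps else None

    return {
        "n_nodes": world.kg.n_nodes,
        "n_edges": world.kg.n_edges,
        "type_census": world.kg.type_census(),
        "n_true_pairs": len(world.truth.true_pairs),
        "n_heldout_pairs": len(world.truth.heldout_pairs),
        "n_decoy_pairs": len(world.truth.decoy_pairs),
        "n_null_pairs": len(world.null_pairs),
        "n_cooc_entries": len(world.cooc),
        "n_documents": world.store.n_documents(),
        "mean_p_true": mean_p(world.truth.true_pairs),
        "mean_p_heldout": mean_p(world.truth.heldout_pairs),
        "mean_p_null": mean_p(world.null_pairs),
    }


def pair_training_data(world: World, embeddings: EmbeddingTable):
    """Labelled 129-feature matrix for the classifier: true pairs vs null pairs.

    Positives are the world's emitted protein-protein edges; negatives are
    the sampled null pairs carrying uniform co-occurrence p-values. Pairs
    without a co-occurrence entry are excluded, never imputed.
    """
    X, y, pairs = [], [], []
    for label, pool in ((1, sorted(world.truth.true_pairs)), (0, world.null_pairs)):
        for u, v in pool:
            p = world.cooc.get(u, v)
            if p is None or u not in embeddings or v not in embeddings:
                continue
            X.append(build_pair_feature(embeddings[u], embeddings[v], p))
            y.append(label)
            pairs.append((u, v))
    return np.array(X), np.array(y), pairs


def make_classifier_fixture(n_pairs: int = 2000, embed_dim: int = 64,
                            embed_separation: float = 0.0,
                            cooc_informative: bool = True,
                            seed: int = 0):
    """Standalone labelled pair-feature dataset for classifier experiments.

    ``embed_separation`` shifts positive-pair embeddings along a fixed
    direction (0 makes the embedding block pure noise); with
    ``cooc_informative`` the co-occurrence p-value is drawn low for
    positives and high for negatives, so the final feature carries class
    signal. The co-occurrence-only setting (separation 0) is the fixture
    for the fusion-ablation comparison.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_pairs)
    direction = np.ones(embed_dim) / np.sqrt(embed_dim)
    Zu = rng.standard_normal((n_pairs, embed_dim)) + np.outer(y * embed_separation, direction)
    Zv = rng.standard_normal((n_pairs, embed_dim)) + np.outer(y * embed_separation, direction)
    if cooc_informative:
        p = np.where(y == 1, rng.beta(1.0, 19.0, n_pairs), rng.beta(19.0, 1.0, n_pairs))
    else:
        p = rng.random(n_pairs)
    X = np.array([build_pair_feature(zu, zv, float(pi))
                  for zu, zv, pi in zip(Zu, Zv, p)])
    return X, y.astype(int)
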