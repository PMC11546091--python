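"""End-to-end discovery: enumerate missing edges, classify, validate, expand.

The workflow mirrors the deployment path of the method: starting from a
(unipartite) knowledge graph, all unconnected node pairs are enumerated;
pairs represented in the co-occurrence table are scored by the fused MLP;
pairs above threshold are looked up in the document store; each mentioning
abstract is validated by the text backend; a pair is confirmed when ANY
document yields a YES verdict. Confirmed pairs become new annotated edges,
and a stage-count audit trail records the cascade.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import InstructionExample, build_instruction
from .docstore import DocumentStore
from .gnn import EmbeddingTable
from .graph import CooccurrenceTable, KnowledgeGraph, canonical_pair
from .mlp import MlpModel, build_pair_feature
from .validator import ValidatorVerdict, validate_pair

logger = logging.getLogger(__name__)

__all__ = [
    "NewEdge",
    "ExpandedNetwork",
    "DiscoveryAudit",
    "filter_by_cooccurrence",
    "enumerate_nonedges",
    "run_discovery",
]

Pair = tuple[str, str]

# Interaction-nature keyword map applied to YES explanations; the fallback
# is an honest "untyped" rather than a guess.
_NATURE_KEYWORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("physical binding", ("binds", "binding", "complex")),
    ("co-localization", ("co-local", "colocal")),
    ("regulatory", ("regulat", "activat", "inhibit", "phosphorylat", "repress")),
)


def _interaction_nature(explanations: Sequence[str]) -> str:
    text = " ".join(explanations).lower()
    for nature, keys in _NATURE_KEYWORDS:
        if any(k in text for k in keys):
            return nature
    return "untyped"


@dataclass(frozen=True)
class NewEdge:
    pair: Pair
    probability: float
    doc_ids: tuple[str, ...]
    verdicts: tuple[ValidatorVerdict, ...]
    nature: str


@dataclass
class DiscoveryAudit:
    """Cascade counts; each stage can only shrink the candidate set."""

    candidates: int = 0
    with_features: int = 0
    classified_positive: int = 0
    with_documents: int = 0
    confirmed: int = 0
    unverified: list[Pair] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "with_features": self.with_features,
            "classified_positive": self.classified_positive,
            "with_documents": self.with_documents,
            "confirmed": self.confirmed,
            "unverified": [list(p) for p in self.unverified],
        }


@dataclass
class ExpandedNetwork:
    base: KnowledgeGraph
    new_edges: list[NewEdge]
    audit: DiscoveryAudit

    def __post_init__(self) -> None:
        for edge in self.new_edges:
            if edge.pair in self.base.edges:
                raise ValueError(f"new edge {edge.pair} already in the base graph")
            if not any(v.is_yes for v in edge.verdicts):
                raise ValueError(f"new edge {edge.pair} lacks a YES verdict")

    def to_json(self, path) -> None:
        payload = {
            "audit": self.audit.as_dict(),
            "new_edges": [
                {
                    "u": e.pair[0],
                    "v": e.pair[1],
                    "probability": e.probability,
                    "doc_ids": list(e.doc_ids),
                    "nature": e.nature,
                    "verdicts": [
                        {
                            "decision": v.decision,
                            "confidence": v.confidence,
                            "explanation": v.explanation,
                            "doc_id": v.doc_id,
                        }
                        for v in e.verdicts
                    ],
                }
                for e in self.new_edges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def edges_to_csv(self, path) -> None:
        rows = [
            {"u": e.pair[0], "v": e.pair[1], "probability": e.probability,
             "nature": e.nature, "n_supporting_docs": len(e.doc_ids)}
            for e in self.new_edges
        ]
        pd.DataFrame(rows, columns=["u", "v", "probability", "nature",
                                    "n_supporting_docs"]).to_csv(path, index=False)


def filter_by_cooccurrence(objects: Sequence[str], query_term: str,
                           store: DocumentStore, alpha: float = 0.05) -> list[str]:
    """Keep objects whose co-occurrence p-value with the query term is
    <= alpha (the filter removes strictly greater); missing p drops the
    object with a warning."""
    kept = []
    for obj in objects:
        p = store.object_pvalue(obj, query_term)
        if p is None:
            logger.warning("object %r has no p-value for query %r; dropped", obj, query_term)
            continue
        if p <= alpha:
            kept.append(obj)
    return kept


def enumerate_nonedges(kg: KnowledgeGraph, nodes: Sequence[str] | None = None) -> list[Pair]:
    """All unordered, canonical pairs within ``nodes`` lacking an edge."""
    subset = sorted(kg.nodes) if nodes is None else sorted(set(nodes))
    unknown = [n for n in subset if n not in kg.nodes]
    if unknown:
        raise ValueError(f"nodes not in graph: {unknown[:5]}")
    return [
        canonical_pair(u, v)
        for u, v in combinations(subset, 2)
        if canonical_pair(u, v) not in kg.edges
    ]


def run_discovery(kg: KnowledgeGraph, cooc: CooccurrenceTable, store: DocumentStore,
                  embeddings: EmbeddingTable, mlp_model: MlpModel,
                  backend: Callable[[str], str],
                  nodes: Sequence[str] | None = None,
                  checkpoint_path=None) -> ExpandedNetwork:
    """Run the full cascade and return the expanded, annotated network.

    Pairs absent from the co-occurrence table are skipped; classified-
    positive pairs without any mentioning document are reported as
    unverified, never added. On a failure during validation, partial
    verdicts are persisted to ``checkpoint_path`` (if given) before the
    error propagates.
    """
    audit = DiscoveryAudit()
    candidates = enumerate_nonedges(kg, nodes)
    audit.candidates = len(candidates)

    featured: list[Pair] = []
    feats: list[np.ndarray] = []
    for u, v in candidates:
        p = cooc.get(u, v)
        if p is None or u not in embeddings or v not in embeddings:
            continue
        featured.append((u, v))
        feats.append(build_pair_feature(embeddings[u], embeddings[v], p))
    audit.with_features = len(featured)

    positives: list[tuple[Pair, float]] = []
    if featured:
        probs = mlp_model.predict_proba(np.vstack(feats))
        for pair, prob in zip(featured, probs):
            if prob > mlp_model.cfg.threshold:
                positives.append((pair, float(prob)))
    audit.classified_positive = len(positives)

    new_edges: list[NewEdge] = []
    processed: list[dict] = []
    try:
        for (u, v), prob in positives:
            docs = store.docs_for_pair(u, v)
            if not docs:
                audit.unverified.append((u, v))
                logger.info("pair (%s, %s) classified positive but has no documents; "
                            "reported unverified", u, v)
                continue
            audit.with_documents += 1
            verdicts = []
            for doc_id, text in docs:
                example = InstructionExample(
                    prompt=build_instruction(text, u, v), pair=(u, v),
                    label=0, doc_id=doc_id)
                verdicts.append(validate_pair(example, backend))
            processed.append({"pair": [u, v],
                              "decisions": [vd.decision for vd in verdicts]})
            yes = [vd for vd in verdicts if vd.is_yes]
            if yes:
                audit.confirmed += 1
                new_edges.append(NewEdge(
                    pair=(u, v), probability=prob,
                    doc_ids=tuple(vd.doc_id for vd in yes),
                    verdicts=tuple(verdicts),
                    nature=_interaction_nature([vd.explanation for vd in yes])))
    except Exception:
        if checkpoint_path is not None:
            Path(checkpoint_path).write_text(json.dumps(
                {"processed": processed, "audit": audit.as_dict()}, indent=1))
            logger.error("discovery failed; checkpoint written to %s", checkpoint_path)
        raise

    return ExpandedNetwork(base=kg, new_edges=new_edges, audit=audit)
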