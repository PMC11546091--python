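"""Heterogeneous knowledge-graph container, CSV I/O and projections.

The associative gene network is a typed, undirected graph: nodes are
molecular-genetic entities (proteins, diseases, drugs, ...) and edges are
literature-derived associations. Edges are stored canonically with
``u < v`` (string order); parallel edges of different interaction types
are collapsed into a single edge carrying the set of type labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Edge",
    "KnowledgeGraph",
    "CooccurrenceTable",
    "GraphIntegrityError",
    "GraphParseError",
    "canonical_pair",
    "load_graph",
    "save_graph",
    "project_unipartite",
    "filter_short_names",
    "cooccurrence_feature",
]


class GraphIntegrityError(ValueError):
    """An edge references a node absent from the node table."""


class GraphParseError(ValueError):
    """A malformed row in a node or edge table; message names the row."""


def canonical_pair(u: str, v: str) -> tuple[str, str]:
    """Order an unordered pair canonically (string comparison); reject self-pairs."""
    u, v = str(u), str(v)
    if u == v:
        raise ValueError(f"self-pair not allowed: {u!r}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Node:
    node_id: str
    name: str
    entity_type: str
    features: tuple[float, ...] = ()


@dataclass(frozen=True)
class Edge:
    """Undirected edge with u < v; ``types`` collapses parallel typed edges."""

    u: str
    v: str
    types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        cu, cv = canonical_pair(self.u, self.v)
        if (cu, cv) != (self.u, self.v):
            raise ValueError(f"edge not canonical: ({self.u}, {self.v})")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.u, self.v)


@dataclass
class KnowledgeGraph:
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, edge in self.edges.items():
            if pair != edge.pair:
                raise ValueError(f"edge keyed by {pair} but stores {edge.pair}")
            for endpoint in pair:
                if endpoint not in self.nodes:
                    raise GraphIntegrityError(
                        f"edge {pair} references unknown node {endpoint!r}"
                    )

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_pair(u, v) in self.edges

    def neighbors(self, node_id: str) -> list[str]:
        out = []
        for (u, v) in self.edges:
            if u == node_id:
                out.append(v)
            elif v == node_id:
                out.append(u)
        return out

    def degree(self, node_id: str) -> int:
        return sum(1 for (u, v) in self.edges if node_id in (u, v))

    def entity_types(self) -> list[str]:
        return sorted({n.entity_type for n in self.nodes.values()})

    def type_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for node in self.nodes.values():
            census[node.entity_type] = census.get(node.entity_type, 0) + 1
        return census

    def add_node(self, node: Node) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, u: str, v: str, types: Iterable[str] = ()) -> None:
        pair = canonical_pair(u, v)
        for endpoint in pair:
            if endpoint not in self.nodes:
                raise GraphIntegrityError(f"edge {pair} references unknown node {endpoint!r}")
        existing = self.edges.get(pair)
        merged = frozenset(types) | (existing.types if existing else frozenset())
        self.edges[pair] = Edge(pair[0], pair[1], merged)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes.values():
            g.add_node(node.node_id, name=node.name, entity_type=node.entity_type)
        for edge in self.edges.values():
            g.add_edge(edge.u, edge.v, types=sorted(edge.types))
        return g


# ---------------------------------------------------------------------------
# CSV I/O: node table columns id,name,type[,feat_*]; edge table u,v,type
# ---------------------------------------------------------------------------

def _as_dataframe(table, required: list[str], what: str) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, dtype=str, keep_default_na=False)
    elif isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(list(table))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GraphParseError(f"{what} table is missing columns {missing}")
    return df


def load_graph(node_table, edge_table) -> KnowledgeGraph:
    """Build a KnowledgeGraph from node and edge tables (paths or DataFrames).

    Symmetric duplicate edge rows are merged; multiple types for the same
    pair are collapsed into the edge's type set. Raises
    :class:`GraphParseError` naming the offending row on malformed input and
    :class:`GraphIntegrityError` when an edge references an unknown node.
    """
    nodes_df = _as_dataframe(node_table, ["id", "name", "type"], "node")
    edges_df = _as_dataframe(edge_table, ["u", "v", "type"], "edge")
    feat_cols = sorted(
        (c for c in nodes_df.columns if str(c).startswith("feat_")),
        key=lambda c: (len(str(c)), str(c)),
    )

    kg = KnowledgeGraph()
    for i, row in enumerate(nodes_df.itertuples(index=False)):
        rec = row._asdict()
        node_id, name, etype = str(rec["id"]), str(rec["name"]), str(rec["type"])
        if not node_id or not etype:
            raise GraphParseError(f"node row {i}: empty id or type")
        try:
            feats = tuple(float(rec[c]) for c in feat_cols)
        except (TypeError, ValueError) as exc:
            raise GraphParseError(f"node row {i}: bad feature value ({exc})") from exc
        try:
            kg.add_node(Node(node_id, name, etype, feats))
        except ValueError as exc:
            raise GraphParseError(f"node row {i}: {exc}") from exc

    for i, row in enumerate(edges_df.itertuples(index=False)):
        rec = row._asdict()
        u, v, etype = str(rec["u"]), str(rec["v"]), str(rec["type"])
        if u == v:
            raise GraphParseError(f"edge row {i}: self-loop on {u!r}")
        types = frozenset(t for t in etype.split(";") if t)
        try:
            kg.add_edge(u, v, types)
        except GraphIntegrityError as exc:
            raise GraphIntegrityError(f"edge row {i}: {exc}") from exc
    return kg


def save_graph(kg: KnowledgeGraph, nodes_path, edges_path) -> None:
    """Write canonical node/edge CSV tables that round-trip via load_graph."""
    n_feat = max((len(n.features) for n in kg.nodes.values()), default=0)
    node_rows = []
    for node_id in sorted(kg.nodes):
        node = kg.nodes[node_id]
        row: dict[str, object] = {"id": node.node_id, "name": node.name, "type": node.entity_type}
        for j in range(n_feat):
            row[f"feat_{j}"] = (repr(float(node.features[j]))
                                if j < len(node.features) else "0.0")
        node_rows.append(row)
    pd.DataFrame(node_rows).to_csv(nodes_path, index=False)

    edge_rows = [
        {"u": e.u, "v": e.v, "type": ";".join(sorted(e.types))}
        for _, e in sorted(kg.edges.items())
    ]
    pd.DataFrame(edge_rows, columns=["u", "v", "type"]).to_csv(edges_path, index=False)


# ---------------------------------------------------------------------------
# Projections and filters
# ---------------------------------------------------------------------------

def project_unipartite(kg: KnowledgeGraph, kept_type: str) -> KnowledgeGraph:
    """Induced subgraph on nodes of ``kept_type``: only direct edges between
    two kept nodes survive; no edges are created through dropped nodes."""
    kept = {nid: n for nid, n in kg.nodes.items() if n.entity_type == kept_type}
    if not kept:
        logger.warning("kept_type %r matches no node; projection is empty", kept_type)
    edges = {
        pair: edge for pair, edge in kg.edges.items() if pair[0] in kept and pair[1] in kept
    }
    return KnowledgeGraph(nodes=kept, edges=edges)


def filter_short_names(kg: KnowledgeGraph, min_chars: int = 5) -> KnowledgeGraph:
    """Drop nodes whose name is shorter than ``min_chars`` (default removes
    names of four characters or less), along with their incident edges."""
    if min_chars < 1:
        raise ValueError(f"min_chars must be >= 1, got {min_chars}")
    kept = {nid: n for nid, n in kg.nodes.items() if len(n.name) >= min_chars}
    edges = {
        pair: edge for pair, edge in kg.edges.items() if pair[0] in kept and pair[1] in kept
    }
    return KnowledgeGraph(nodes=kept, edges=edges)


def cooccurrence_feature(p: float) -> float:
    """Map a co-occurrence p-value to the classifier feature 1 - p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    return 1.0 - p


class CooccurrenceTable:
    """Canonical pair -> co-occurrence p-value. A missing pair is a distinct
    state (the pair is excluded downstream), never an implicit p = 1."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._p: dict[tuple[str, str], float] = {}
        for (u, v), p in (entries or {}).items():
            self.set(u, v, p)

    def set(self, u: str, v: str, p: float) -> None:
        if not 0.0 <= float(p) <= 1.0:
            raise ValueError(f"p-value must lie in [0, 1], got {p} for pair ({u}, {v})")
        self._p[canonical_pair(u, v)] = float(p)

    def get(self, u: str, v: str) -> float | None:
        return self._p.get(canonical_pair(u, v))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._p

    def __len__(self) -> int:
        return len(self._p)

    def items(self):
        return self._p.items()

    def feature(self, u: str, v: str) -> float | None:
        """1 - p for the pair, or None when the pair is not represented."""
        p = self.get(u, v)
        return None if p is None else cooccurrence_feature(p)

    @classmethod
    def from_csv(cls, path) -> "CooccurrenceTable":
        df = pd.read_csv(path, dtype={"u": str, "v": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.set(row.u, row.v, float(row.p_value))
        return table

    def to_csv(self, path) -> None:
        rows = [
            {"u": u, "v": v, "p_value": repr(p)}
            for (u, v), p in sorted(self._p.items())
        ]
        pd.DataFrame(rows, columns=["u", "v", "p_value"]).to_csv(path, index=False)
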