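"""GraphSAGE-style link predictor over the knowledge graph.

A two-layer mean-aggregation graph encoder maps node features to
128-dimensional hidden states (ReLU) and then to 64-dimensional
embeddings z_u. An edge (u, v) is scored by the dot product
s(u, v) = sum_i z_u[i] * z_v[i], trained with binary cross-entropy on
logits against sampled non-edges (one negative per positive), using
AdamW at learning rate 0.01 and early stopping on validation loss with
a patience of 20 epochs. Each layer combines a self term with the mean
of the neighbours: h' = act(h W_self + mean_{n in N(u)} h_n W_neigh + b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from . import _nn
from .graph import KnowledgeGraph, canonical_pair
from .metrics import confusion, report

logger = logging.getLogger(__name__)

__all__ = [
    "GnnConfig",
    "EmbeddingTable",
    "LinkSplit",
    "GnnTrainResult",
    "ConfigurationError",
    "TrainingDivergenceError",
    "node_feature_matrix",
    "split_links",
    "encode",
    "link_score",
    "train_gnn",
    "evaluate_link_f1",
    "shuffled_label_f1",
]

Pair = tuple[str, str]


class ConfigurationError(ValueError):
    """Graph or configuration unfit for the requested training run."""


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite; message carries the epoch index."""


@dataclass(frozen=True)
class GnnConfig:
    hidden_dim: int = 128
    out_dim: int = 64
    learning_rate: float = 0.01
    weight_decay: float = 0.01
    patience: int = 20
    val_fraction: float = 0.1
    test_fraction: float = 0.05
    max_epochs: int = 1000
    negative_sampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.out_dim <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 < self.val_fraction + self.test_fraction < 1:
            raise ValueError("val_fraction + test_fraction must lie in (0, 1)")


class EmbeddingTable:
    """node_id -> embedding vector; all vectors share one length."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        lengths = {len(v) for v in vectors.values()}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent embedding lengths: {sorted(lengths)}")
        self._vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        self.dim = lengths.pop()

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self._vectors[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def items(self):
        return self._vectors.items()

    def to_csv(self, path) -> None:
        rows = [
            {"node_id": nid, **{f"e{i}": repr(float(x)) for i, x in enumerate(vec)}}
            for nid, vec in sorted(self._vectors.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingTable":
        df = pd.read_csv(path, dtype={"node_id": str})
        cols = [c for c in df.columns if c.startswith("e")]
        cols.sort(key=lambda c: int(c[1:]))
        return cls({row.node_id: np.array([getattr(row, c) for c in cols], dtype=float)
                    for row in df.itertuples(index=False)})


@dataclass
class LinkSplit:
    """Disjoint positive edge partitions with matched sampled non-edges."""

    train_pos: list[Pair]
    val_pos: list[Pair]
    test_pos: list[Pair]
    train_neg: list[Pair]
    val_neg: list[Pair]
    test_neg: list[Pair]


def node_feature_matrix(kg: KnowledgeGraph, node_ids: Sequence[str]) -> np.ndarray:
    """Feature matrix row-aligned with ``node_ids``, z-score normalised.

    Uses the feat_* columns shipped with the graph when present; otherwise
    falls back to [degree, one-hot entity type].
    """
    if all(len(kg.nodes[nid].features) > 0 for nid in node_ids):
        raw = np.array([kg.nodes[nid].features for nid in node_ids], dtype=float)
    else:
        types = kg.entity_types()
        type_index = {t: i for i, t in enumerate(types)}
        degree = {nid: 0 for nid in node_ids}
        for (u, v) in kg.edges:
            if u in degree:
                degree[u] += 1
            if v in degree:
                degree[v] += 1
        raw = np.zeros((len(node_ids), 1 + len(types)))
        for row, nid in enumerate(node_ids):
            raw[row, 0] = degree[nid]
            raw[row, 1 + type_index[kg.nodes[nid].entity_type]] = 1.0
    return StandardScaler().fit_transform(raw)


def _sample_nonedges(rng: np.random.Generator, node_ids: Sequence[str],
                     forbidden: set[Pair], count: int) -> list[Pair]:
    """Sample ``count`` distinct canonical non-edges avoiding ``forbidden``."""
    n = len(node_ids)
    if count > n * (n - 1) // 2 - len(forbidden):
        raise ConfigurationError("graph too dense to sample the requested negatives")
    chosen: set[Pair] = set()
    out: list[Pair] = []
    while len(out) < count:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = canonical_pair(node_ids[i], node_ids[j])
        if pair in forbidden or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return out


def split_links(kg: KnowledgeGraph, cfg: GnnConfig) -> LinkSplit:
    """Partition edges into train/val/test with matched 1:1 negatives.

    |val| = round(val_fraction * |E|), |test| = round(test_fraction * |E|),
    the remainder trains. Negatives are non-edges of the *full* graph,
    disjoint across partitions. Reproducible for a fixed config seed.
    """
    if kg.n_edges < 20:
        raise ConfigurationError(f"need at least 20 edges, graph has {kg.n_edges}")
    rng = np.random.default_rng(cfg.seed)
    edges = sorted(kg.edges)
    order = rng.permutation(len(edges))
    n_val = round(cfg.val_fraction * len(edges))
    n_test = round(cfg.test_fraction * len(edges))
    n_train = len(edges) - n_val - n_test
    if min(n_val, n_test, n_train) <= 0:
        raise ConfigurationError(
            f"split of {len(edges)} edges leaves an empty partition "
            f"(train={n_train}, val={n_val}, test={n_test})"
        )
    val_pos = [edges[i] for i in order[:n_val]]
    test_pos = [edges[i] for i in order[n_val:n_val + n_test]]
    train_pos = [edges[i] for i in order[n_val + n_test:]]

    node_ids = sorted(kg.nodes)
    forbidden = set(edges)
    train_neg = _sample_nonedges(rng, node_ids, forbidden, n_train)
    val_neg = _sample_nonedges(rng, node_ids, forbidden | set(train_neg), n_val)
    test_neg = _sample_nonedges(rng, node_ids, forbidden | set(train_neg) | set(val_neg), n_test)
    return LinkSplit(train_pos, val_pos, test_pos, train_neg, val_neg, test_neg)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

def init_params(rng: np.random.Generator, in_dim: int, cfg: GnnConfig) -> dict[str, np.ndarray]:
    Ws1, b1 = _nn.init_linear(rng, in_dim, cfg.hidden_dim)
    Wn1, _ = _nn.init_linear(rng, in_dim, cfg.hidden_dim)
    Ws2, b2 = _nn.init_linear(rng, cfg.hidden_dim, cfg.out_dim)
    Wn2, _ = _nn.init_linear(rng, cfg.hidden_dim, cfg.out_dim)
    return {"Ws1": Ws1, "Wn1": Wn1, "b1": b1, "Ws2": Ws2, "Wn2": Wn2, "b2": b2}


def _mean_adjacency(n: int, edge_index: np.ndarray) -> np.ndarray:
    """Row-normalised adjacency (dense); isolated nodes keep a zero row."""
    M = np.zeros((n, n))
    if edge_index.size:
        M[edge_index[:, 0], edge_index[:, 1]] = 1.0
        M[edge_index[:, 1], edge_index[:, 0]] = 1.0
    deg = M.sum(axis=1, keepdims=True)
    np.divide(M, deg, out=M, where=deg > 0)
    return M


def encode(features: np.ndarray, edge_index: np.ndarray,
           params: dict[str, np.ndarray]) -> np.ndarray:
    """Forward pass: features -> ReLU(mean-agg to hidden) -> embeddings.

    ``edge_index`` is an (m, 2) array of undirected node-index pairs used
    for message passing. Deterministic given the parameters.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1] != params["Ws1"].shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match weights {params['Ws1'].shape[0]}"
        )
    M = _mean_adjacency(X.shape[0], np.asarray(edge_index, dtype=int).reshape(-1, 2))
    pre1 = X @ params["Ws1"] + (M @ X) @ params["Wn1"] + params["b1"]
    H1 = _nn.relu(pre1)
    return H1 @ params["Ws2"] + (M @ H1) @ params["Wn2"] + params["b2"]


def _forward_cached(X: np.ndarray, M: np.ndarray, params: dict[str, np.ndarray]):
    MX = M @ X
    pre1 = X @ params["Ws1"] + MX @ params["Wn1"] + params["b1"]
    H1 = _nn.relu(pre1)
    MH1 = M @ H1
    Z = H1 @ params["Ws2"] + MH1 @ params["Wn2"] + params["b2"]
    return Z, (MX, pre1, H1, MH1)


def _backward(X, M, params, cache, dZ):
    MX, pre1, H1, MH1 = cache
    grads = {
        "Ws2": H1.T @ dZ,
        "Wn2": MH1.T @ dZ,
        "b2": dZ.sum(axis=0),
    }
    dH1 = dZ @ params["Ws2"].T + M.T @ (dZ @ params["Wn2"].T)
    dpre1 = dH1 * (pre1 > 0)
    grads["Ws1"] = X.T @ dpre1
    grads["Wn1"] = MX.T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    return grads


def link_score(z_u: np.ndarray, z_v: np.ndarray) -> float:
    """Dot-product edge score s(u, v) = sum_i z_u[i] * z_v[i]."""
    z_u = np.asarray(z_u, dtype=float)
    z_v = np.asarray(z_v, dtype=float)
    if z_u.shape != z_v.shape:
        raise ValueError(f"embedding shape mismatch: {z_u.shape} vs {z_v.shape}")
    return float(np.dot(z_u, z_v))


def _pair_logits(Z: np.ndarray, u_idx: np.ndarray, v_idx: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", Z[u_idx], Z[v_idx])


@dataclass
class GnnTrainResult:
    """Best-epoch model outputs.

    ``embeddings`` are the deployment embeddings, computed with every
    observed edge as a message edge (candidate non-edges are not in the
    graph, so nothing leaks). Evaluation embeddings follow the standard
    link-split protocol: validation sees train message edges only,
    test sees train+validation message edges.
    """

    embeddings: EmbeddingTable
    val_embeddings: EmbeddingTable
    test_embeddings: EmbeddingTable
    history: list[dict] = field(default_factory=list)
    split: LinkSplit | None = None
    best_epoch: int = 0
    val_f1: float = 0.0
    test_f1: float = 0.0


def train_gnn(kg: KnowledgeGraph, cfg: GnnConfig) -> GnnTrainResult:
    """Train the link predictor; return best-validation-epoch embeddings.

    Train negatives are resampled every epoch; validation/test negatives
    stay frozen from the split. Stops when validation loss has not
    improved for ``cfg.patience`` epochs.
    """
    split = split_links(kg, cfg)
    node_ids = sorted(kg.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    X = node_feature_matrix(kg, node_ids)

    def to_idx(pairs: Sequence[Pair]) -> np.ndarray:
        return np.array([(index[u], index[v]) for u, v in pairs], dtype=int).reshape(-1, 2)

    msg_edges = to_idx(split.train_pos)
    M = _mean_adjacency(len(node_ids), msg_edges)

    rng = np.random.default_rng(cfg.seed + 1)
    params = init_params(rng, X.shape[1], cfg)
    opt = _nn.AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    train_pos = msg_edges
    val_pos, val_neg = to_idx(split.val_pos), to_idx(split.val_neg)
    all_edges = set(kg.edges)

    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        if cfg.negative_sampling:
            neg_pairs = _sample_nonedges(rng, node_ids, all_edges, len(split.train_pos))
            train_neg = to_idx(neg_pairs)
        else:
            train_neg = to_idx(split.train_neg)

        Z, cache = _forward_cached(X, M, params)
        u_idx = np.concatenate([train_pos[:, 0], train_neg[:, 0]])
        v_idx = np.concatenate([train_pos[:, 1], train_neg[:, 1]])
        labels = np.concatenate([np.ones(len(train_pos)), np.zeros(len(train_neg))])
        logits = _pair_logits(Z, u_idx, v_idx)
        loss = _nn.bce_with_logits(logits, labels)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(f"non-finite training loss at epoch {epoch}")

        g = (_nn.sigmoid(logits) - labels) / len(labels)
        dZ = np.zeros_like(Z)
        np.add.at(dZ, u_idx, g[:, None] * Z[v_idx])
        np.add.at(dZ, v_idx, g[:, None] * Z[u_idx])
        opt.step(_backward(X, M, params, cache, dZ))

        Z_eval, _ = _forward_cached(X, M, params)
        vu = np.concatenate([val_pos[:, 0], val_neg[:, 0]])
        vv = np.concatenate([val_pos[:, 1], val_neg[:, 1]])
        vy = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])
        v_logits = _pair_logits(Z_eval, vu, vv)
        val_loss = _nn.bce_with_logits(v_logits, vy)
        val_f1 = report(confusion((v_logits > 0).astype(int).tolist(),
                                  vy.astype(int).tolist())).f1
        history.append({"epoch": epoch, "train_loss": loss,
                        "val_loss": val_loss, "val_f1": val_f1})

        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break

    def table_for(message_edges: np.ndarray) -> EmbeddingTable:
        M_stage = _mean_adjacency(len(node_ids), message_edges)
        Z_stage, _ = _forward_cached(X, M_stage, best_params)
        return EmbeddingTable({nid: Z_stage[i] for nid, i in index.items()})

    val_table = table_for(msg_edges)
    test_table = table_for(to_idx(split.train_pos + split.val_pos))
    deploy_table = table_for(to_idx(sorted(kg.edges)))
    result = GnnTrainResult(
        embeddings=deploy_table, val_embeddings=val_table,
        test_embeddings=test_table, history=history, split=split,
        best_epoch=best_epoch)
    result.val_f1 = evaluate_link_f1(val_table, split.val_pos, split.val_neg)
    result.test_f1 = evaluate_link_f1(test_table, split.test_pos, split.test_neg)
    return result


def shuffled_label_f1(embeddings: EmbeddingTable, positives: Sequence[Pair],
                      negatives: Sequence[Pair], seed: int = 0) -> float:
    """Permutation-null F1: scores kept, edge labels randomly permuted.

    Destroying the score-label correspondence while keeping the score
    distribution and class balance fixed yields the chance level of the
    F1 statistic (~0.5 on balanced sets); a trained model evaluated this
    way should collapse to it.
    """
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be nonempty")
    rng = np.random.default_rng(seed)
    pairs = list(positives) + list(negatives)
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    labels = rng.permutation(labels)
    preds = [int(link_score(embeddings[u], embeddings[v]) > 0) for u, v in pairs]
    return report(confusion(preds, labels.tolist())).f1


def evaluate_link_f1(embeddings: EmbeddingTable, positives: Sequence[Pair],
                     negatives: Sequence[Pair]) -> float:
    """F1 of dot-product link scores thresholded at logit 0 (probability 0.5)."""
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be nonempty")
    preds, truth = [], []
    for label, pairs in ((1, positives), (0, negatives)):
        for u, v in pairs:
            preds.append(int(link_score(embeddings[u], embeddings[v]) > 0))
            truth.append(label)
    return report(confusion(preds, truth)).f1
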