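"""Fused-feature MLP scoring candidate protein pairs for interaction.

The input is a 129-long vector: the two 64-dimensional node embeddings
z_u and z_v concatenated, followed by the literature co-occurrence
feature 1 - p. Architecture 129 -> 256 -> 128 -> 64 -> 1 with ReLU
activations and a logistic output; trained with binary cross-entropy,
AdamW at learning rate 0.001, mini-batches of 64, and early stopping on
validation MCC with a patience of 50 epochs. A prediction counts as
positive only when the probability is strictly above the threshold
(exactly 0.5 is negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn
from .metrics import ConfusionMatrix, confusion, mcc
from .gnn import ConfigurationError, TrainingDivergenceError

logger = logging.getLogger(__name__)

__all__ = [
    "EMBED_DIM",
    "PAIR_FEATURE_DIM",
    "MlpConfig",
    "MlpModel",
    "PairPrediction",
    "build_pair_feature",
    "ablate_cooccurrence",
    "mlp_predict",
    "train_mlp",
]

EMBED_DIM = 64
PAIR_FEATURE_DIM = 2 * EMBED_DIM + 1  # z_u || z_v || (1 - p)


def build_pair_feature(z_u: np.ndarray, z_v: np.ndarray, p: float) -> np.ndarray:
    """Concatenate [z_u (64) | z_v (64) | 1 - p] into the 129-long feature."""
    z_u = np.asarray(z_u, dtype=float)
    z_v = np.asarray(z_v, dtype=float)
    if z_u.shape != (EMBED_DIM,) or z_v.shape != (EMBED_DIM,):
        raise ValueError(
            f"embeddings must have length {EMBED_DIM}, got {z_u.shape} and {z_v.shape}"
        )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    return np.concatenate([z_u, z_v, [1.0 - p]])


def ablate_cooccurrence(features: np.ndarray) -> np.ndarray:
    """Drop the co-occurrence slot (last column), leaving the 128 embedding
    entries untouched — the ablation experiment's input."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    mat = features.reshape(1, -1) if single else features
    if mat.shape[1] != PAIR_FEATURE_DIM:
        raise ValueError(f"expected width {PAIR_FEATURE_DIM}, got {mat.shape[1]}")
    out = mat[:, :-1]
    return out[0] if single else out


@dataclass(frozen=True)
class MlpConfig:
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 0.001
    weight_decay: float = 0.01
    batch_size: int = 64
    patience: int = 50
    max_epochs: int = 300
    threshold: float = 0.5
    val_fraction: float = 0.1
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PairPrediction:
    pair: tuple[str, str] | None
    probability: float
    label: int


class MlpModel:
    """Feed-forward network with ReLU hidden layers and a logistic output."""

    def __init__(self, in_dim: int, cfg: MlpConfig, params: dict[str, np.ndarray] | None = None):
        self.in_dim = in_dim
        self.cfg = cfg
        self.params = params
        self.history: list[dict] = []
        self.best_epoch: int | None = None

    # -- lifecycle --------------------------------------------------------
    def initialize(self, rng: np.random.Generator) -> None:
        sizes = [self.in_dim, *self.cfg.hidden_sizes, 1]
        params: dict[str, np.ndarray] = {}
        for layer, (fan_in, fan_out) in enumerate(zip(sizes, sizes[1:])):
            W, b = _nn.init_linear(rng, fan_in, fan_out)
            params[f"W{layer}"] = W
            params[f"b{layer}"] = b
        self.params = params

    def _require_params(self) -> dict[str, np.ndarray]:
        if self.params is None:
            raise RuntimeError("model is neither trained nor initialized")
        return self.params

    @property
    def n_layers(self) -> int:
        return len(self.cfg.hidden_sizes) + 1

    # -- inference --------------------------------------------------------
    def _forward(self, X: np.ndarray):
        params = self._require_params()
        acts = [X]
        pres = []
        h = X
        for layer in range(self.n_layers):
            pre = h @ params[f"W{layer}"] + params[f"b{layer}"]
            pres.append(pre)
            h = pre if layer == self.n_layers - 1 else _nn.relu(pre)
            acts.append(h)
        return acts, pres

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.in_dim:
            raise ValueError(f"expected feature width {self.in_dim}, got {X.shape[1]}")
        acts, _ = self._forward(X)
        return acts[-1][:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > self.cfg.threshold).astype(int)

    # -- training ---------------------------------------------------------
    def _batch_grads(self, X: np.ndarray, y: np.ndarray):
        params = self._require_params()
        acts, pres = self._forward(X)
        logits = acts[-1][:, 0]
        loss = _nn.bce_with_logits(logits, y)
        delta = ((_nn.sigmoid(logits) - y) / len(y))[:, None]
        grads: dict[str, np.ndarray] = {}
        for layer in range(self.n_layers - 1, -1, -1):
            grads[f"W{layer}"] = acts[layer].T @ delta
            grads[f"b{layer}"] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ params[f"W{layer}"].T) * (pres[layer - 1] > 0)
        return loss, grads


def mlp_predict(model: MlpModel, feature: np.ndarray,
                pair: tuple[str, str] | None = None) -> PairPrediction:
    """Score one pair feature; the label is positive iff probability > threshold."""
    prob = float(model.predict_proba(np.asarray(feature, dtype=float).reshape(1, -1))[0])
    return PairPrediction(pair=pair, probability=prob,
                          label=int(prob > model.cfg.threshold))


def _stratified_split(X, y, cfg: MlpConfig):
    holdout = cfg.val_fraction + cfg.test_fraction
    X_train, X_rest, y_train, y_rest = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=cfg.seed)
    X_val, X_test, y_val, y_test = train_test_split(
        X_rest, y_rest, test_size=cfg.test_fraction / holdout,
        stratify=y_rest, random_state=cfg.seed)
    return (X_train, y_train), (X_val, y_val), (X_test, y_test)


def _val_mcc(model: MlpModel, X_val: np.ndarray, y_val: np.ndarray) -> float:
    preds = model.predict(X_val)
    return mcc(confusion(preds.tolist(), y_val.astype(int).tolist()))


def train_mlp(X: np.ndarray, y: np.ndarray, cfg: MlpConfig) -> MlpModel:
    """Train on a labelled feature matrix; return the best-validation-MCC model.

    The dataset is split 80/10/10 stratified (seeded). Raises
    :class:`ConfigurationError` when either class is missing from the
    training or validation split (MCC is degenerate there).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature matrix and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training data must contain both classes")
    (X_train, y_train), (X_val, y_val), _ = _stratified_split(X, y, cfg)
    if len(np.unique(y_val)) < 2:
        raise ConfigurationError("validation split is single-class; MCC degenerate")

    rng = np.random.default_rng(cfg.seed)
    model = MlpModel(X.shape[1], cfg)
    model.initialize(rng)
    opt = _nn.AdamW(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    best_mcc = -np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = 0
    n = len(X_train)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model._batch_grads(X_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            opt.step(grads)
        val_mcc = _val_mcc(model, X_val, y_val)
        model.history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                              "val_mcc": val_mcc})
        if val_mcc > best_mcc:
            best_mcc = val_mcc
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best %d, MCC %.4f)",
                        epoch, best_epoch, best_mcc)
            break

    model.params = best_params
    model.best_epoch = best_epoch
    return model
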