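"""Minimal NumPy neural-network primitives shared by the GNN and the MLP.

Implements exactly what the two models need: ReLU, numerically stable
sigmoid / binary cross-entropy on logits, seeded uniform fan-in weight
initialisation, and a decoupled-weight-decay Adam optimiser (AdamW).
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "sigmoid", "bce_with_logits", "init_linear", "AdamW"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    expx = np.exp(x[~pos])
    out[~pos] = expx / (1.0 + expx)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy computed on logits (log-sum-exp form)."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    # log(1 + exp(-|x|)) + max(x, 0) - x*y is stable for any sign of x
    loss = np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0.0) - logits * labels
    return float(np.mean(loss))


def init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform fan-in initialisation: W ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    weight = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    bias = rng.uniform(-bound, bound, size=fan_out)
    return weight, bias


class AdamW:
    """Adam with decoupled weight decay over a dict of named parameters.

    Decay is applied to weight matrices only (names starting with 'W'),
    matching the usual practice of exempting biases.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}
        self._t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for key, param in self.params.items():
            g = grads[key]
            self._m[key] = b1 * self._m[key] + (1 - b1) * g
            self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            m_hat = self._m[key] / (1 - b1 ** self._t)
            v_hat = self._v[key] / (1 - b2 ** self._t)
            if self.weight_decay and key.startswith("W"):
                param -= self.lr * self.weight_decay * param
            param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
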