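"""Sequential network with weighted cross-entropy training and saliency.

Training is plain minibatch SGD with epoch-level early stopping: stop when
the loss on a held-aside early-stopping set has not improved for `patience`
consecutive epochs, then restore the best-epoch weights.  Per-class loss
weights correct class imbalance.

``input_gradient`` backpropagates the target-class logit to the input
image; with ``guided=True`` every rectifier additionally zeroes negative
upstream gradients (guided backpropagation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .layers import Layer, ReLU

__all__ = ["Sequential", "TrainingConfig", "softmax", "weighted_ce_loss"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_ce_loss(logits: np.ndarray, y: np.ndarray,
                     class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    w = class_weights[y]
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), y] + eps)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def forward_upto(self, x: np.ndarray, n_layers: int) -> np.ndarray:
        """Activations after the first ``n_layers`` layers."""
        for layer in self.layers[:n_layers]:
            x = layer.forward(x)
        return x

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers if layer.trainable
                for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers if layer.trainable
                for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def weight_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for p in [q for layer in self.layers for q in layer.params]:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_early: np.ndarray, y_early: np.ndarray,
            class_weights: np.ndarray,
            config: TrainingConfig) -> dict:
        """SGD with patience-based early stopping on (X_early, y_early).

        Returns a history dict with per-epoch train and early-stop losses
        and the selected stopping epoch (best early-stop loss).
        """
        rng = np.random.default_rng(config.seed)
        n = len(y)
        best_loss = np.inf
        best_weights = self.get_weights()
        best_epoch = -1
        history = {"train_loss": [], "early_stop_loss": []}
        since_improve = 0
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = self.forward(X[idx])
                loss, grad = weighted_ce_loss(logits, y[idx], class_weights)
                self.backward(grad)
                for p, g in zip(self.parameters(), self.gradients()):
                    p -= config.learning_rate * g
                epoch_loss += loss
                n_batches += 1
            es_logits = self.predict_logits(X_early)
            es_loss, _ = weighted_ce_loss(es_logits, y_early, class_weights)
            history["train_loss"].append(epoch_loss / max(n_batches, 1))
            history["early_stop_loss"].append(es_loss)
            if es_loss < best_loss - 1e-12:
                best_loss = es_loss
                best_weights = self.get_weights()
                best_epoch = epoch
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    break
        self.set_weights(best_weights)
        history["best_epoch"] = best_epoch
        return history

    # -- inference ----------------------------------------------------------
    def predict_logits(self, X: np.ndarray,
                       batch_size: int = 256) -> np.ndarray:
        outs = []
        for start in range(0, len(X), batch_size):
            outs.append(self.forward(X[start : start + batch_size]))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(X))

    # -- saliency -----------------------------------------------------------
    def input_gradient(self, x: np.ndarray, target_class: int,
                       guided: bool = False) -> np.ndarray:
        """Gradient of the target-class logit with respect to the input.

        ``guided`` switches every rectifier to guided-backprop mode for
        this single backward pass.
        """
        logits = self.forward(x)
        grad = np.zeros_like(logits)
        grad[..., target_class] = 1.0
        relus = [l for l in self.layers if isinstance(l, ReLU)]
        try:
            if guided:
                for r in relus:
                    r.guided = True
            gin = self.backward(grad)
        finally:
            for r in relus:
                r.guided = False
        return gin
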