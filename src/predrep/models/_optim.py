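"""Shared training machinery: RMSprop, plateau schedule, early stopping."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "RMSprop", "PlateauScheduler", "EarlyStopping"]


class SGD:
    """Plain stochastic gradient descent: p <- p - lr * g."""

    def __init__(self, learning_rate: float):
        self.learning_rate = learning_rate

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for key, g in grads.items():
            params[key] -= self.learning_rate * g


class RMSprop:
    """RMSprop with running squared-gradient average.

    v <- alpha * v + (1 - alpha) * g^2 ;  p <- p - lr * g / (sqrt(v) + eps)
    """

    def __init__(self, learning_rate: float = 1e-4, alpha: float = 0.95, eps: float = 1e-7):
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.eps = eps
        self._cache: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for key, g in grads.items():
            v = self._cache.get(key)
            if v is None:
                v = np.zeros_like(g)
            v = self.alpha * v + (1.0 - self.alpha) * g * g
            self._cache[key] = v
            params[key] -= self.learning_rate * g / (np.sqrt(v) + self.eps)


class PlateauScheduler:
    """Halve the learning rate when validation loss stops decreasing."""

    def __init__(self, optimizer: RMSprop, factor: float = 0.5, patience: int = 8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self._best = np.inf
        self._stale = 0

    def update(self, val_loss: float) -> None:
        if val_loss < self._best:
            self._best = val_loss
            self._stale = 0
        else:
            self._stale += 1
            if self._stale >= self.patience:
                self.optimizer.learning_rate *= self.factor
                self._stale = 0


class EarlyStopping:
    """Stop after `patience` epochs without improvement beyond `min_delta`."""

    def __init__(self, patience: int = 25, min_delta: float = 5e-5):
        self.patience = patience
        self.min_delta = min_delta
        self._best = np.inf
        self._stale = 0

    def should_stop(self, val_loss: float) -> bool:
        if val_loss < self._best - self.min_delta:
            self._best = val_loss
            self._stale = 0
        else:
            self._stale += 1
        return self._stale >= self.patience
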