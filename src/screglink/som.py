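"""A seeded 1-D self-organizing map for clustering temporal curves.

Classic online SOM on a 1-D unit grid with a Gaussian neighborhood, linearly
decaying learning rate and neighborhood width.  ``epochs`` counts single-
sample update steps (one randomly drawn sample per step).  All randomness
flows from the explicit seed, so identical seeds and inputs give identical
codebooks and assignments.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["SelfOrganizingMap1D"]

_SIGMA_FLOOR = 0.1
_LR_FLOOR = 0.01


class SelfOrganizingMap1D:
    def __init__(
        self,
        m_units: int,
        epochs: int = 2000,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        seed: int | None = None,
    ):
        if m_units < 1:
            raise ValidationError("m_units must be >= 1")
        if epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if seed is None:
            raise ValidationError("an explicit seed is required for reproducibility")
        self.m_units = int(m_units)
        self.epochs = int(epochs)
        self.learning_rate = float(learning_rate)
        self.sigma = float(sigma) if sigma is not None else max(m_units / 2.0, 0.5)
        self.seed = int(seed)
        self.codebook_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap1D":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or len(X) < self.m_units:
            raise ValidationError(
                f"need a 2-D array with at least {self.m_units} samples, got {X.shape}"
            )
        rng = np.random.default_rng(self.seed)
        init_idx = rng.choice(len(X), size=self.m_units, replace=False)
        codebook = X[init_idx].copy()
        grid = np.arange(self.m_units, dtype=np.float64)
        for step in range(self.epochs):
            frac = step / self.epochs
            lr = max(self.learning_rate * (1.0 - frac), _LR_FLOOR)
            sig = max(self.sigma * (1.0 - frac), _SIGMA_FLOOR)
            x = X[rng.integers(len(X))]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-((grid - bmu) ** 2) / (2.0 * sig**2))
            codebook += lr * h[:, None] * (x - codebook)
        self.codebook_ = codebook
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.codebook_ is None:
            raise ValidationError("SOM is not fitted")
        X = np.asarray(X, dtype=np.float64)
        d2 = ((X[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)
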