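"""Input normalization with strict train-only statistics.

Three column-wise strategies are supported, matching the hyperparameter
axis explored for the network:

``norm``            standardize to zero mean, unit variance;
``norm_tanh``       standardize, then squash through tanh (bounded (-1, 1));
``norm_tanh_norm``  standardize, tanh, then standardize again with a second
                    set of statistics computed on the tanh-transformed
                    training data.

All statistics come from training rows only; applying a fitted normalizer
never refits.  Zero-variance columns store a standard deviation of 1 so the
transform stays defined when a fold reintroduces a constant column.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["Normalizer", "STRATEGIES"]

STRATEGIES = ("norm", "norm_tanh", "norm_tanh_norm")


class Normalizer:
    """Column-wise normalizer; fit on training rows, apply anywhere."""

    def __init__(self, strategy: str = "norm"):
        if strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
        self.strategy = strategy
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.mean2_: np.ndarray | None = None
        self.std2_: np.ndarray | None = None

    @staticmethod
    def _safe_std(x: np.ndarray) -> np.ndarray:
        std = x.std(axis=0, ddof=0)
        std[std == 0] = 1.0
        return std

    def fit(self, train: np.ndarray) -> "Normalizer":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ValueError("training matrix is empty")
        if not np.all(np.isfinite(train)):
            rows, cols = np.where(~np.isfinite(train))
            raise ValueError(
                f"non-finite training entries, first at row {rows[0]}, column {cols[0]}"
            )
        self.mean_ = train.mean(axis=0)
        self.std_ = self._safe_std(train)
        if self.strategy == "norm_tanh_norm":
            squashed = np.tanh((train - self.mean_) / self.std_)
            self.mean2_ = squashed.mean(axis=0)
            self.std2_ = self._safe_std(squashed)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer is not fitted")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"column count {matrix.shape[1]} does not match the "
                f"{self.mean_.shape[0]} columns seen at fit time"
            )
        z = (matrix - self.mean_) / self.std_
        if self.strategy == "norm":
            return z
        z = np.tanh(z)
        if self.strategy == "norm_tanh":
            return z
        return (z - self.mean2_) / self.std2_

    def fit_transform(self, train: np.ndarray) -> np.ndarray:
        return self.fit(train).transform(train)

    # -- persistence: flat key-value JSON inside a saved-model directory ----

    def to_dict(self) -> dict:
        state = {"strategy": self.strategy}
        for key in ("mean_", "std_", "mean2_", "std2_"):
            val = getattr(self, key)
            state[key] = None if val is None else np.asarray(val).tolist()
        return state

    @classmethod
    def from_dict(cls, state: dict) -> "Normalizer":
        norm = cls(state["strategy"])
        for key in ("mean_", "std_", "mean2_", "std2_"):
            val = state.get(key)
            setattr(norm, key, None if val is None else np.asarray(val, dtype=float))
        return norm

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Normalizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
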