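"""Extreme learning machine (ELM) classifier.

A single-hidden-layer feed-forward network in which the input-to-hidden
weights and hidden biases are drawn once, uniformly in [-1, 1], and only
the hidden-to-output weights are learned — by minimum-norm least squares
against one-hot (+1/0) class targets.  Training therefore costs one matrix
factorization, which is what makes the ELM viable as the inner classifier
of a wrapper feature selector that calls it tens of thousands of times.

Inputs are standardized inside :func:`elm_train` (per-feature mean 0, SD 1;
constant features map to 0) because a sigmoid hidden layer saturates on raw
expression scales; the standardization parameters are stored in the model
and re-applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ELMModel", "elm_train", "elm_predict", "default_hidden_size"]


def default_hidden_size(n_train: int) -> int:
    """Default hidden-layer width: min(100, 2 * n_train).

    Bounded by the sample count so a 60-sample expression dataset does not
    get a trivially huge random feature map.
    """
    return int(min(100, 2 * n_train))


def _activate(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    if kind == "tanh":
        return np.tanh(Z)
    raise ValueError(f"unknown activation {kind!r}; expected 'sigmoid' or 'tanh'")


@dataclass
class ELMModel:
    input_weights: np.ndarray   # (L, d)
    hidden_biases: np.ndarray   # (L,)
    output_weights: np.ndarray  # (L, K)
    activation: str
    class_map: list             # class identifiers, first-appearance order
    feature_center: np.ndarray  # (d,)
    feature_scale: np.ndarray   # (d,)
    seed: int

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_center) / self.feature_scale
        return _activate(Xs @ self.input_weights.T + self.hidden_biases,
                         self.activation)


def elm_train(X, y, L: int | None = None, activation: str = "sigmoid",
              seed: int = 0) -> ELMModel:
    """Train an ELM classifier.

    Hidden weights and biases are drawn uniformly in [-1, 1] from a
    generator seeded with ``seed``; each hidden unit's parameters are drawn
    as one contiguous block, so models with larger ``L`` on the same seed
    share their first hidden units (nested random feature maps).  Output
    weights are the minimum-norm least-squares solution against one-hot
    targets, so the same (X, y, L, seed) always yields an identical model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if d < 1:
        raise ValueError("need at least one feature")
    if len(y) != n:
        raise ValueError("y length does not match X")

    class_map: list = []
    for lab in y.tolist():
        if lab not in class_map:
            class_map.append(lab)
    K = len(class_map)
    if K < 2:
        raise ValueError("y contains a single class; cannot train a classifier")
    if n < K:
        raise ValueError(f"need at least {K} samples for {K} classes")
    if L is None:
        L = default_hidden_size(n)
    if L <= 0:
        raise ValueError("hidden-layer size L must be positive")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant features -> 0 after scaling

    rng = np.random.default_rng(seed)
    block = rng.uniform(-1.0, 1.0, size=(L, d + 1))  # per-unit weights + bias
    W, b = block[:, :d], block[:, d]

    Xs = (X - center) / scale
    H = _activate(Xs @ W.T + b, activation)

    index = {c: k for k, c in enumerate(class_map)}
    T = np.zeros((n, K))
    T[np.arange(n), [index[lab] for lab in y.tolist()]] = 1.0

    B, *_ = np.linalg.lstsq(H, T, rcond=None)  # minimum-norm LS
    return ELMModel(W, b, B, activation, class_map, center, scale, int(seed))


def elm_predict(model: ELMModel, X) -> np.ndarray:
    """Predict class labels; ties broken toward the earlier class in class_map."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X must have {model.n_features} columns, got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.asarray([], dtype=np.asarray(model.class_map).dtype)
    scores = model.hidden_activations(X) @ model.output_weights
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: earlier class
    return np.asarray([model.class_map[i] for i in idx])
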