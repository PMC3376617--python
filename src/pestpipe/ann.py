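"""Three-layer back-propagation classifier.

A fully connected feedforward network with one hidden layer and
logistic-sigmoid activations in both layers, trained by online (per
sample) gradient descent on squared error — the classic delta rule.
Inputs are the 13 image features min-max normalized to [0, 1] with
bounds learned from the training set only; targets are one-hot class
indicator vectors.  The trained weights, thresholds and normalization
bounds serialize to a versioned JSON file so a model fitted offline can
be shipped to the device that runs inference.

The hidden-layer width follows the rule-of-thumb
``n1 = round(sqrt(n_in + n_out)) + a`` with the experiential integer
``a`` in 1..10; for 13 inputs and 6 classes, a = 6 gives the default 10
hidden nodes.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, TrainingError

_MAGIC = "pestpipe-ann-model"
_VERSION = 1


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max learned from the training matrix."""

    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "min_", np.asarray(self.min_, dtype=float))
        object.__setattr__(self, "max_", np.asarray(self.max_, dtype=float))
        if self.min_.shape != self.max_.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.max_ < self.min_):
            raise ValueError("max < min")

    @classmethod
    def fit(cls, X: np.ndarray) -> "NormalizationParams":
        X = np.asarray(X, dtype=float)
        return cls(min_=X.min(axis=0), max_=X.max(axis=0))


def normalize(x: np.ndarray, p: NormalizationParams) -> np.ndarray:
    """Min-max scale features to [0, 1] with training-set bounds.

    Constant features (max == min) map to 0; values outside the
    training range — possible at test time since the bounds are never
    refitted — are clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != p.min_.shape[0]:
        raise ValueError(
            f"feature length {x.shape[-1]} != fitted length {p.min_.shape[0]}"
        )
    span = p.max_ - p.min_
    safe = np.where(span > 0, span, 1.0)
    out = (x - p.min_) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def hidden_size(n: int, m: int, a: int) -> int:
    """Hidden-node count heuristic: round(sqrt(n + m)) + a."""
    if not (1 <= a <= 10):
        raise ValueError("a must be an integer in [1, 10]")
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    return int(math.floor(math.sqrt(n + m) + 0.5)) + a


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    max_epochs: int = 5000
    target_mse: float = 1e-3
    seed: int = 0
    a_heuristic: int = 6
    soft_targets: bool = False  # encode targets as 0.1/0.9 instead of 0/1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.target_mse < 0:
            raise ValueError("target_mse must be nonnegative")


@dataclass
class AnnModel:
    """Weights, thresholds and normalization bounds of the network.

    ``W1`` is (n_hidden, n_in), ``W2`` is (n_out, n_hidden); ``b1`` and
    ``b2`` are the corresponding threshold vectors.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    norm: NormalizationParams
    class_names: list[str]
    training_mse: list[float] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(model: AnnModel, x: np.ndarray) -> np.ndarray:
    """Class-score vector for one already-normalized input.

    h = sigma(W1 x + b1), y = sigma(W2 h + b2); every score lies in
    (0, 1).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_in,):
        raise ValueError(f"expected input shape ({model.n_in},), got {x.shape}")
    h = _sigmoid(model.W1 @ x + model.b1)
    return _sigmoid(model.W2 @ h + model.b2)


def _forward_states(W1, b1, W2, b2, x):
    h = _sigmoid(W1 @ x + b1)
    y = _sigmoid(W2 @ h + b2)
    return h, y


def sample_loss(W1, b1, W2, b2, x, t) -> float:
    """Per-sample squared-error loss E = 1/2 * sum (y - t)^2."""
    _, y = _forward_states(W1, b1, W2, b2, x)
    return 0.5 * float(np.sum((y - t) ** 2))


def gradients(W1, b1, W2, b2, x, t):
    """Delta-rule gradients of :func:`sample_loss` w.r.t. all parameters."""
    h, y = _forward_states(W1, b1, W2, b2, x)
    delta_out = (y - t) * y * (1.0 - y)
    delta_hid = (W2.T @ delta_out) * h * (1.0 - h)
    gW2 = np.outer(delta_out, h)
    gb2 = delta_out
    gW1 = np.outer(delta_hid, x)
    gb1 = delta_hid
    return gW1, gb1, gW2, gb2


def train(
    X: np.ndarray,
    labels,
    cfg: TrainConfig = TrainConfig(),
    n_hidden: int | None = None,
    class_names: list[str] | None = None,
) -> AnnModel:
    """Fit the network to labeled feature vectors.

    Normalization bounds are fitted on ``X``; training is online
    gradient descent in a freshly shuffled sample order each epoch,
    stopping at ``target_mse`` (mean over samples and outputs of the
    squared output error) or ``max_epochs``.  Fully deterministic given
    ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise TrainingError("X must be a nonempty (n_samples, n_features) matrix")
    if np.any(~np.isfinite(X)):
        raise TrainingError("non-finite feature values")
    labels = list(labels)
    if len(labels) != len(X):
        raise TrainingError("labels/X length mismatch")
    if class_names is None:
        class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise TrainingError("need at least 2 classes")
    idx_of = {c: i for i, c in enumerate(class_names)}
    try:
        y_idx = np.array([idx_of[l] for l in labels])
    except KeyError as e:
        raise TrainingError(f"label {e} not in class_names") from e

    n_samples, n_in = X.shape
    n_out = len(class_names)
    if n_hidden is None:
        n_hidden = hidden_size(n_in, n_out, cfg.a_heuristic)

    norm = NormalizationParams.fit(X)
    Xn = normalize(X, norm)
    lo, hi = (0.1, 0.9) if cfg.soft_targets else (0.0, 1.0)
    T = np.full((n_samples, n_out), lo)
    T[np.arange(n_samples), y_idx] = hi

    rng = np.random.default_rng(cfg.seed)
    W1 = rng.uniform(-0.5, 0.5, size=(n_hidden, n_in))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    W2 = rng.uniform(-0.5, 0.5, size=(n_out, n_hidden))
    b2 = rng.uniform(-0.5, 0.5, size=n_out)

    lr = cfg.learning_rate
    history = []
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n_samples)
        for i in order:
            gW1, gb1, gW2, gb2 = gradients(W1, b1, W2, b2, Xn[i], T[i])
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2
        H = _sigmoid(Xn @ W1.T + b1)
        Y = _sigmoid(H @ W2.T + b2)
        mse = float(np.mean((Y - T) ** 2))
        history.append(mse)
        if mse <= cfg.target_mse:
            break

    return AnnModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        norm=norm, class_names=list(class_names), training_mse=history,
    )


def predict(model: AnnModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Normalize a raw feature vector, run the network, argmax the scores.

    Ties go to the lowest class index.  Returns (label, score vector).
    """
    scores = forward(model, normalize(x, model.norm))
    return model.class_names[int(np.argmax(scores))], scores


def save_model(model: AnnModel, path) -> None:
    doc = {
        "magic": _MAGIC,
        "version": _VERSION,
        "n_in": model.n_in,
        "n_hidden": model.n_hidden,
        "n_out": model.n_out,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "feature_min": model.norm.min_.tolist(),
        "feature_max": model.norm.max_.tolist(),
        "class_names": model.class_names,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> AnnModel:
    if not os.path.exists(path):
        raise ModelError(f"model file not found: {path}")
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as e:
        raise ModelError(f"cannot read model file {path}: {e}") from e
    if not isinstance(doc, dict) or doc.get("magic") != _MAGIC:
        raise ModelError(f"{path} is not a pestpipe ANN model file")
    if doc.get("version") != _VERSION:
        raise ModelError(f"unsupported model version {doc.get('version')}")
    model = AnnModel(
        W1=np.asarray(doc["W1"], dtype=float),
        b1=np.asarray(doc["b1"], dtype=float),
        W2=np.asarray(doc["W2"], dtype=float),
        b2=np.asarray(doc["b2"], dtype=float),
        norm=NormalizationParams(doc["feature_min"], doc["feature_max"]),
        class_names=list(doc["class_names"]),
    )
    if model.W1.shape != (doc["n_hidden"], doc["n_in"]) or model.W2.shape != (
        doc["n_out"],
        doc["n_hidden"],
    ):
        raise ModelError("model weight shapes inconsistent with header")
    if len(model.class_names) != model.n_out:
        raise ModelError("class_names length != n_out")
    return model
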