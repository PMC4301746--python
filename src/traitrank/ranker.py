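"""Feed-forward neural relevance ranker and its training.

The network maps the 11 relevance features of a hit to a scalar score:
11 input neurons, two hidden layers of 16 and 8 neurons, one output
neuron, with a sigmoid activation at every layer.  Training is
full-batch gradient descent on mean squared error against graded
feedback targets; the five feedback classes are mapped to equally
spaced targets on [0, 1].
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import N_FEATURES

LAYER_SIZES = (N_FEATURES, 16, 8, 1)

#: The five ordered relevance classes of the graded feedback protocol,
#: from least to most relevant, with equally spaced numeric targets.
RELEVANCE_LABELS = (
    "no relevance",
    "undecided",
    "could be of relevance",
    "minor quality doubts",
    "fully agree",
)

N_RELEVANCE_CLASSES = len(RELEVANCE_LABELS)

_LABEL_TARGETS = {
    label: i / (N_RELEVANCE_CLASSES - 1) for i, label in enumerate(RELEVANCE_LABELS)
}


def label_to_target(label: str) -> float:
    """Numeric training target of a relevance class label.

    ``"no relevance"`` maps to 0.0 and ``"fully agree"`` to 1.0, with the
    intermediate classes equally spaced.
    """
    try:
        return _LABEL_TARGETS[label]
    except KeyError:
        raise ValueError(
            f"unknown relevance label {label!r}; valid labels: {list(RELEVANCE_LABELS)}"
        ) from None


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainingConfig:
    learning_rate: float = 0.5
    epochs: int = 2000
    seed: int = 0


@dataclass
class RankerNetwork:
    """Weights and biases of the 11-16-8-1 sigmoid network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = list(zip(LAYER_SIZES[1:], LAYER_SIZES[:-1]))
        shapes = [w.shape for w in self.weights]
        if shapes != expected:
            raise ValueError(f"weight shapes {shapes} != expected {expected}")
        if [b.shape for b in self.biases] != [(n,) for n, _ in expected]:
            raise ValueError("bias shapes inconsistent with layer sizes")
        for arr in (*self.weights, *self.biases):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")

    # -- inference -----------------------------------------------------

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer for a batch ``X`` of shape (n, 11)."""
        activations = [np.asarray(X, dtype=float)]
        for W, b in zip(self.weights, self.biases):
            activations.append(sigmoid(activations[-1] @ W.T + b))
        return activations

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != LAYER_SIZES[0]:
            raise ValueError(
                f"expected feature matrix of width {LAYER_SIZES[0]}, got shape {X.shape}"
            )
        return self.forward(X)[-1][:, 0]

    def predict(self, features: Sequence[float]) -> float:
        x = np.asarray(features, dtype=float)
        if x.shape != (LAYER_SIZES[0],):
            raise ValueError(
                f"expected {LAYER_SIZES[0]} features, got shape {x.shape}"
            )
        return float(self.predict_batch(x[None, :])[0])

    # -- persistence ---------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "format": "traitrank-network",
            "version": 1,
            "layer_sizes": list(LAYER_SIZES),
            "activation": "sigmoid",
            "weights": [w.ravel().tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json_dict(cls, d: dict) -> "RankerNetwork":
        if d.get("layer_sizes") != list(LAYER_SIZES):
            raise ValueError(f"unsupported layer sizes: {d.get('layer_sizes')}")
        weights = [
            np.asarray(vals, dtype=float).reshape(n_out, n_in)
            for vals, (n_out, n_in) in zip(
                d["weights"], zip(LAYER_SIZES[1:], LAYER_SIZES[:-1])
            )
        ]
        biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return cls(weights, biases, seed=d.get("seed"), metadata=d.get("metadata", {}))

    @classmethod
    def load(cls, path: str | Path) -> "RankerNetwork":
        return cls.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def copy(self) -> "RankerNetwork":
        return RankerNetwork(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            seed=self.seed,
            metadata=dict(self.metadata),
        )


def init_network(seed: int) -> RankerNetwork:
    """Fresh network with weights drawn uniformly from [-0.5, 0.5]."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_out, n_in)))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out))
    return RankerNetwork(weights, biases, seed=seed)


def mse_loss(network: RankerNetwork, X: np.ndarray, t: np.ndarray) -> float:
    pred = network.predict_batch(X)
    return float(np.mean((pred - t) ** 2))


def gradients(
    network: RankerNetwork, X: np.ndarray, t: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backpropagation gradients of the MSE loss w.r.t. all parameters."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    n = X.shape[0]
    activations = network.forward(X)
    y = activations[-1][:, 0]
    # dL/dy for L = mean (y - t)^2
    delta = (2.0 / n) * (y - t)[:, None] * (activations[-1] * (1 - activations[-1]))
    grad_w: list[np.ndarray] = [None] * len(network.weights)  # type: ignore
    grad_b: list[np.ndarray] = [None] * len(network.biases)  # type: ignore
    for layer in range(len(network.weights) - 1, -1, -1):
        grad_w[layer] = delta.T @ activations[layer]
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            a = activations[layer]
            delta = (delta @ network.weights[layer]) * a * (1 - a)
    return grad_w, grad_b


def train(
    network: RankerNetwork,
    examples: Iterable[tuple[Sequence[float], float]],
    config: TrainingConfig | None = None,
) -> RankerNetwork:
    """Full-batch gradient descent on MSE; returns a new network.

    An empty example list returns an unchanged copy.  Raises on
    non-finite loss (diverging learning rate).
    """
    config = config or TrainingConfig()
    examples = list(examples)
    result = network.copy()
    if not examples:
        return result
    X = np.asarray([f for f, _ in examples], dtype=float)
    t = np.asarray([target for _, target in examples], dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("training targets must lie in [0, 1]")
    initial = mse_loss(result, X, t)
    for _ in range(config.epochs):
        grad_w, grad_b = gradients(result, X, t)
        for W, gW in zip(result.weights, grad_w):
            W -= config.learning_rate * gW
        for b, gb in zip(result.biases, grad_b):
            b -= config.learning_rate * gb
    final = mse_loss(result, X, t)
    if not np.isfinite(final):
        raise FloatingPointError("training diverged to a non-finite loss")
    result.metadata = {
        **result.metadata,
        "trained_on": len(examples),
        "epochs": config.epochs,
        "learning_rate": config.learning_rate,
        "initial_mse": initial,
        "final_mse": final,
    }
    return result


def rank(
    network: RankerNetwork, hits: Sequence[tuple[str, Sequence[float]]]
) -> list[tuple[str, float, list[float]]]:
    """Order hits by descending predicted score; ties by record_id.

    Returns ``(record_id, score, feature_vector)`` triples.
    """
    if not hits:
        return []
    X = np.asarray([f for _, f in hits], dtype=float)
    scores = network.predict_batch(X)
    out = [
        (rec_id, float(s), list(map(float, f)))
        for (rec_id, f), s in zip(hits, scores)
    ]
    out.sort(key=lambda r: (-r[1], r[0]))
    return out


# -- feedback storage -------------------------------------------------

FEEDBACK_COLUMNS = ("profile", "query", "record_id", "label", "timestamp")


def append_feedback(
    path: str | Path,
    profile: str,
    query: str,
    record_id: str,
    label: str,
    timestamp: float | None = None,
) -> None:
    """Append one graded judgment to the append-only feedback TSV."""
    label_to_target(label)  # validate
    if timestamp is None:
        timestamp = time.time()
    new = not Path(path).exists()
    with Path(path).open("a", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if new:
            writer.writerow(FEEDBACK_COLUMNS)
        writer.writerow([profile, query, record_id, label, repr(timestamp)])


def read_feedback(path: str | Path, profile: str | None = None) -> list[dict]:
    """Read feedback rows, optionally restricted to one profile."""
    rows = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if profile is None or row["profile"] == profile:
                rows.append(row)
    return rows
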