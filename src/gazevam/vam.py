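"""The visual attention model: a small per-pixel fixedness classifier.

One VAM per group. The network is a single hidden layer of 10 sigmoid units
feeding one linear output unit, trained with per-sample stochastic gradient
descent on binary cross-entropy (learning rate 0.01, up to 1000 epochs or
mean epoch loss below 1e-7). The linear output is interpreted as a logit:
BCE needs a probability, so a logistic link is applied inside the loss and
at prediction — the only numerically coherent reading of a linear output
paired with cross-entropy.

Applied to every pixel of a frame's feature stack and thresholded at 0.5,
a VAM yields the group's binary saliency map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import CHANNEL_NAMES, FeatureStack

N_HIDDEN = 10


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 1000
    loss_tolerance: float = 1e-7   # on the mean epoch loss
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs <= 0 or self.learning_rate <= 0 or self.loss_tolerance <= 0:
            raise ValueError("all TrainConfig values must be positive")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class VAModel:
    """Trained weights + per-feature min-max normalization + provenance."""

    W1: np.ndarray                # (10, d)
    b1: np.ndarray                # (10,)
    w2: np.ndarray                # (10,)
    b2: float
    norm_lo: np.ndarray           # (d,)
    norm_span: np.ndarray         # (d,)
    group: str | None = None
    feature_indices: np.ndarray | None = None  # into the 28-channel registry
    epochs_run: int = 0
    final_loss: float = float("nan")
    seed: int = 0
    loss_history: list[float] | None = None  # mean BCE per epoch

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    def _check(self, X):
        if X.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[-1]}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fixedness probability in [0, 1] for one vector or a batch."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        self._check(X)
        Xn = (X - self.norm_lo) / self.norm_span
        h = _sigmoid(Xn @ self.W1.T + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    def save(self, path) -> Path:
        path = Path(path)
        doc = {
            "format": "gazevam-vam-1",
            "group": self.group,
            "epochs_run": self.epochs_run,
            "final_loss": self.final_loss,
            "seed": self.seed,
            "feature_indices": None if self.feature_indices is None
                               else [int(i) for i in self.feature_indices],
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": float(self.b2),
            "norm_lo": self.norm_lo.tolist(), "norm_span": self.norm_span.tolist(),
        }
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def load(cls, path) -> "VAModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "gazevam-vam-1":
            raise ValueError(f"{path}: not a gazevam VAM file")
        fi = doc["feature_indices"]
        return cls(np.array(doc["W1"]), np.array(doc["b1"]), np.array(doc["w2"]),
                   doc["b2"], np.array(doc["norm_lo"]), np.array(doc["norm_span"]),
                   group=doc["group"],
                   feature_indices=None if fi is None else np.array(fi),
                   epochs_run=doc["epochs_run"], final_loss=doc["final_loss"],
                   seed=doc["seed"])


def predict_pixel(model: VAModel, vector: np.ndarray) -> float:
    """Probability that one pixel (feature vector) is fixated."""
    return float(model.predict(np.asarray(vector))[0])


def train_vam(X: np.ndarray, y: np.ndarray, cfg: TrainConfig = TrainConfig(),
              group: str | None = None,
              feature_indices: np.ndarray | None = None) -> VAModel:
    """Fit the 10-hidden-unit network with per-sample SGD on BCE.

    Features are min-max normalized on the training set (the state is stored
    and re-applied at prediction). Samples are reshuffled each epoch with a
    seeded generator, so training is deterministic for a fixed seed. Stops at
    ``max_epochs`` or when the mean epoch loss drops below the tolerance.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with matching y")
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("training labels are single-class; need both 0 and 1")
    if not set(uniq).issubset({0.0, 1.0}):
        raise ValueError("labels must be binary 0/1")

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Xn = (X - lo) / span

    rng = np.random.default_rng(cfg.seed)
    d = X.shape[1]
    W1 = rng.uniform(-0.5, 0.5, (N_HIDDEN, d))
    b1 = np.zeros(N_HIDDEN)
    w2 = rng.uniform(-0.5, 0.5, N_HIDDEN)
    b2 = 0.0
    lr = cfg.learning_rate

    n = len(y)
    epoch = 0
    loss = np.inf
    loss_history: list[float] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        total = 0.0
        for i in order:
            x = Xn[i]
            h = _sigmoid(W1 @ x + b1)
            z = w2 @ h + b2
            p = _sigmoid(z)
            eps = 1e-12
            total += -(y[i] * np.log(p + eps) + (1 - y[i]) * np.log(1 - p + eps))
            dz = p - y[i]
            dh = dz * w2 * h * (1 - h)
            w2 -= lr * dz * h
            b2 -= lr * dz
            W1 -= lr * np.outer(dh, x)
            b1 -= lr * dh
        loss = total / n
        loss_history.append(float(loss))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss}, "
                f"|W1|max={np.abs(W1).max():.3g}")
        if loss < cfg.loss_tolerance:
            break

    return VAModel(W1, b1, w2, b2, lo, span, group=group,
                   feature_indices=feature_indices,
                   epochs_run=epoch, final_loss=float(loss), seed=cfg.seed,
                   loss_history=loss_history)


def binary_saliency_map(model: VAModel, stack: FeatureStack,
                        threshold: float = 0.5) -> np.ndarray:
    """Predict fixedness for every pixel of a (mean) feature stack.

    Uses the model's stored feature subset when present. A probability
    >= 0.5 maps to 1 (the boundary counts as fixated). Returns a binary
    uint8 map of the frame shape.
    """
    ch = stack.channels
    if model.feature_indices is not None:
        ch = ch[model.feature_indices]
    if ch.shape[0] != model.n_features:
        raise ValueError(f"stack provides {ch.shape[0]} channels; model wants {model.n_features}")
    h, w = ch.shape[1:]
    X = ch.reshape(ch.shape[0], -1).T
    p = model.predict(X)
    return (p >= threshold).astype(np.uint8).reshape(h, w)
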