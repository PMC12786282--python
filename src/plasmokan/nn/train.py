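"""Training loop: Adam on clipped binary cross-entropy, with learning curves.

The objective is ``BCE(y, p) = -1/N sum[y_i log p_i + (1-y_i) log(1-p_i)]``
with predictions clipped to ``[eps, 1-eps]`` (eps = 1e-7).  The gradient is
taken through the sigmoid analytically (``dL/dz = (p - y)/N``), which is the
numerically stable form of the same objective.  Everything is seeded and runs
single-threaded numpy, so identical configs give identical learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .models import Module, sigmoid

BCE_EPS = 1e-7


def bce_loss(labels: np.ndarray, predictions: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy with prediction clipping."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have the same shape")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 10

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patience) < 1 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    n_parameters: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]

    @property
    def best_val_auc(self) -> float:
        return self.val_auc[self.best_epoch]


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.grad
            v[...] = self.b2 * v + (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def predict(model: Module, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    """Per-record probabilities, evaluated in batches."""
    out = []
    for start in range(0, X.shape[0], batch_size):
        out.append(sigmoid(model.forward(X[start : start + batch_size])))
    return np.concatenate(out)


def subject_scores(probabilities: np.ndarray, subject_ids) -> "pd.Series":
    """Subject-level score: mean probability over a subject's replicate records."""
    import pandas as pd

    return pd.Series(probabilities, index=pd.Index(subject_ids, name="subject_id")).groupby(
        level=0
    ).mean()


def train(
    model: Module,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Optimize the model on BCE, early-stopping on validation loss.

    Returns the learning curves; the model is left at the best-validation
    checkpoint.  Raises on divergence (non-finite loss).
    """
    config = config if config is not None else TrainConfig()
    if X_train.shape[0] != y_train.shape[0] or X_val.shape[0] != y_val.shape[0]:
        raise ValueError("feature/label lengths disagree")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), config.learning_rate)
    result = TrainResult(n_parameters=model.n_parameters)
    best_state: list[np.ndarray] | None = None
    best_loss = np.inf
    stale = 0
    n = X_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model.forward(xb)
            probs = sigmoid(logits)
            loss = bce_loss(yb, probs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}, "
                    f"|logit|max={np.max(np.abs(logits))}"
                )
            epoch_loss += loss * len(idx)
            model.zero_grad()
            model.backward((probs - yb) / len(idx))
            opt.step()
        result.train_loss.append(epoch_loss / n)

        val_probs = predict(model, X_val)
        vloss = bce_loss(y_val, val_probs)
        result.val_loss.append(vloss)
        if len(np.unique(y_val)) < 2:
            result.val_auc.append(float("nan"))
        else:
            result.val_auc.append(float(roc_auc_score(y_val, val_probs)))
        result.val_accuracy.append(float(np.mean((val_probs >= 0.5) == (y_val == 1))))

        if vloss < best_loss - 1e-12:
            best_loss = vloss
            best_state = model.state_arrays()
            result.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return result
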