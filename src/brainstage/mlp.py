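"""A seeded feed-forward classifier with inter-layer dropout.

Architecture: input → ``hidden_layers`` dense ReLU layers of ``hidden_units``
each (inverted dropout between them, L2 weight decay on all weights) →
softmax output, trained with mini-batch Adam and early stopping on an inner
stratified train/validation split.  Written directly on numpy so that
training is bit-reproducible under a fixed seed in single-threaded runs,
which the evaluation protocol relies on.

Implements the scikit-learn estimator API (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``) and composes with
pipelines and ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["MLPDropoutClassifier"]


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPDropoutClassifier(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron with dropout, L2 decay, Adam and early stopping.

    Parameters
    ----------
    hidden_layers : number of hidden ReLU layers (default 9).
    hidden_units : units per hidden layer (default 128; the layer count is
        specified by the protocol, the width is a free choice).
    learning_rate : Adam step size (default 0.01).
    batch_size : mini-batch size (default 32).
    epochs : maximum training epochs (default 50).
    dropout : drop probability between hidden layers (default 0.3).
    l2 : weight-decay coefficient; the loss gains l2·Σ‖W‖² (default 1e-3).
    patience : epochs of non-improving validation loss before stopping
        (default 10); the best-validation weights are restored.
    validation_fraction : inner hold-out fraction for early stopping
        (default 0.2, i.e. an 80:20 inner split), stratified.
    random_state : seed for initialisation, shuffling, dropout and the split.
    """

    def __init__(
        self,
        hidden_layers: int = 9,
        hidden_units: int = 128,
        learning_rate: float = 0.01,
        batch_size: int = 32,
        epochs: int = 50,
        dropout: float = 0.3,
        l2: float = 0.001,
        patience: int = 10,
        validation_fraction: float = 0.2,
        random_state: int | None = 0,
    ) -> None:
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout = dropout
        self.l2 = l2
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "MLPDropoutClassifier":
        X, y = validate_data(self, X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        if self.validation_fraction > 0 and counts.min() < 2:
            raise ValueError(
                "every class needs >= 2 samples for the inner validation split"
            )
        rng = np.random.default_rng(self.random_state)

        if self.validation_fraction > 0:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y_idx,
                test_size=self.validation_fraction,
                stratify=y_idx,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            X_tr, y_tr = X, y_idx
            X_val = y_val = None

        widths = [X.shape[1]] + [self.hidden_units] * self.hidden_layers + [n_classes]
        W = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        b = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(bb) for bb in b]
        vb = [np.zeros_like(bb) for bb in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        n = X_tr.shape[0]
        best_loss = np.inf
        best = None
        stale = 0
        self.loss_curve_: list[float] = []
        self.validation_loss_curve_: list[float] = []

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X_tr[idx], y_tr[idx]
                # forward with inverted dropout between hidden layers
                acts = [xb]
                masks = []
                a = xb
                for li in range(self.hidden_layers):
                    a = _relu(a @ W[li] + b[li])
                    if self.dropout > 0:
                        mask = (
                            rng.random(a.shape) >= self.dropout
                        ) / (1.0 - self.dropout)
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    acts.append(a)
                logits = a @ W[-1] + b[-1]
                probs = _softmax(logits)
                onehot = np.eye(len(self.classes_))[yb]
                ce = -np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()
                epoch_loss += ce * len(yb)
                # backward
                delta = (probs - onehot) / len(yb)
                gW = [None] * len(W)
                gb = [None] * len(W)
                gW[-1] = acts[-1].T @ delta + 2.0 * self.l2 * W[-1]
                gb[-1] = delta.sum(axis=0)
                for li in range(self.hidden_layers - 1, -1, -1):
                    delta = delta @ W[li + 1].T
                    if masks[li] is not None:
                        delta = delta * masks[li]
                    delta = delta * (acts[li + 1] > 0)
                    gW[li] = acts[li].T @ delta + 2.0 * self.l2 * W[li]
                    gb[li] = delta.sum(axis=0)
                t += 1
                for li in range(len(W)):
                    mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                    vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                    mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                    mhW = mW[li] / (1 - beta1**t)
                    vhW = vW[li] / (1 - beta2**t)
                    mhb = mb[li] / (1 - beta1**t)
                    vhb = vb[li] / (1 - beta2**t)
                    W[li] -= self.learning_rate * mhW / (np.sqrt(vhW) + eps)
                    b[li] -= self.learning_rate * mhb / (np.sqrt(vhb) + eps)
            self.loss_curve_.append(epoch_loss / n)

            if X_val is not None:
                val_probs = self._forward(X_val, W, b)
                val_loss = -np.log(
                    val_probs[np.arange(len(y_val)), y_val] + 1e-12
                ).mean()
                self.validation_loss_curve_.append(float(val_loss))
                if val_loss < best_loss - 1e-9:
                    best_loss = val_loss
                    best = ([w.copy() for w in W], [bb.copy() for bb in b])
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break

        if best is not None:
            W, b = best
        self.weights_, self.biases_ = W, b
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def _forward(self, X: np.ndarray, W, b) -> np.ndarray:
        a = X
        for li in range(self.hidden_layers):
            a = _relu(a @ W[li] + b[li])
        return _softmax(a @ W[-1] + b[-1])

    # -------------------------------------------------------------- predict

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=np.float64)
        return self._forward(X, self.weights_, self.biases_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
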