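"""Multi-output regression head mapping tile embeddings to marker z-scores.

The head is a four-layer fully connected network ``d → h1 → h2 → h3 → M``
(GELU between layers, optional dropout) trained with Adam on mean squared
error summed over the M markers, with early stopping on a held-out
validation split. A ``architecture="linear"`` variant — a single linear map
``d → M`` — serves the mean-color baseline.

Implemented as a scikit-learn-style estimator: constructor takes
hyperparameters only, ``fit`` learns ``weights_``/``history_``, ``predict``
maps embeddings to an ``(n, M)`` z-score matrix. Training is fully
deterministic given ``random_state``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import erf
from sklearn.base import BaseEstimator, RegressorMixin

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))

def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)

def _relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)

_ACTIVATIONS = {"gelu": (_gelu, _gelu_grad), "relu": (_relu, _relu_grad)}


class ExpressionRegressor(RegressorMixin, BaseEstimator):
    """Embedding → marker-expression regression head.

    Parameters
    ----------
    architecture : "mlp" or "linear"
        Four-layer fully connected head, or a single linear layer.
    hidden_sizes : widths of the three hidden layers (mlp only).
    activation : "gelu" or "relu".
    dropout : hidden-unit dropout probability at training time.
    learning_rate, batch_size, max_epochs : Adam training schedule.
    patience : early-stopping patience, in epochs without validation
        improvement; the best-validation weights are restored.
    random_state : seeds initialization, shuffling and dropout; identical
        seeds give bit-identical histories and predictions.
    """

    def __init__(
        self,
        architecture: str = "mlp",
        hidden_sizes: tuple[int, ...] = (256, 256, 256),
        activation: str = "gelu",
        dropout: float = 0.1,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 300,
        patience: int = 10,
        weight_decay: float = 0.0,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _init_weights(self, d: int, M: int, rng: np.random.Generator):
        sizes = (
            [d, M]
            if self.architecture == "linear"
            else [d, *self.hidden_sizes, M]
        )
        Ws, bs = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            Ws.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            bs.append(np.zeros(fan_out))
        return Ws, bs

    def _forward(self, X, Ws, bs, rng=None):
        """Forward pass; returns output and per-layer caches for backprop."""
        act, _ = _ACTIVATIONS[self.activation]
        a = X
        caches = []
        for k, (W, b) in enumerate(zip(Ws, bs)):
            z = a @ W + b
            if k < len(Ws) - 1:
                h = act(z)
                if rng is not None and self.dropout > 0:
                    keep = rng.uniform(size=h.shape) >= self.dropout
                    h = h * keep / (1.0 - self.dropout)
                else:
                    keep = None
                caches.append((a, z, keep))
                a = h
            else:
                caches.append((a, z, None))
                a = z
        return a, caches

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(
                f"misaligned inputs: X {X.shape} vs y {y.shape}"
            )
        bad = np.nonzero(~np.isfinite(y).all(axis=1))[0]
        if bad.size:
            raise ValueError(
                f"non-finite regression targets at tile rows {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite embedding values")
        have_val = X_val is not None and y_val is not None
        if have_val:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
            if y_val.ndim == 1:
                y_val = y_val[:, None]
            if X_val.shape[1] != X.shape[1]:
                raise ValueError(
                    f"embedding dim mismatch: train d={X.shape[1]}, val d={X_val.shape[1]}"
                )

        n, d = X.shape
        M = y.shape[1]
        # standardize inputs on train statistics (stored for predict)
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = np.maximum(X.std(axis=0), 1e-8)
        X = (X - self.x_mean_) / self.x_scale_
        if have_val:
            X_val = (X_val - self.x_mean_) / self.x_scale_
        rng = np.random.default_rng(self.random_state)
        Ws, bs = self._init_weights(d, M, rng)
        mW = [np.zeros_like(W) for W in Ws]
        vW = [np.zeros_like(W) for W in Ws]
        mb = [np.zeros_like(b) for b in bs]
        vb = [np.zeros_like(b) for b in bs]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        _, act_grad = _ACTIVATIONS[self.activation]

        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = None
        stall = 0
        step = 0
        bsz = min(self.batch_size, n)

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, bsz):
                idx = order[start : start + bsz]
                Xb, yb = X[idx], y[idx]
                out, caches = self._forward(Xb, Ws, bs, rng=rng)
                resid = out - yb
                ep_loss += float((resid**2).sum())
                # backprop: loss = mean over rows of squared error summed over M
                grad = 2.0 * resid / Xb.shape[0]
                gWs = [None] * len(Ws)
                gbs = [None] * len(bs)
                for k in range(len(Ws) - 1, -1, -1):
                    a_in, z, keep = caches[k]
                    if k < len(Ws) - 1:
                        if keep is not None:
                            grad = grad * keep / (1.0 - self.dropout)
                        grad = grad * act_grad(z)
                    gWs[k] = a_in.T @ grad
                    gbs[k] = grad.sum(axis=0)
                    if k > 0:
                        grad = grad @ Ws[k].T
                step += 1
                lr_t = (
                    self.learning_rate
                    * np.sqrt(1 - beta2**step)
                    / (1 - beta1**step)
                )
                for k in range(len(Ws)):
                    if self.weight_decay:
                        gWs[k] = gWs[k] + self.weight_decay * Ws[k]
                    mW[k] = beta1 * mW[k] + (1 - beta1) * gWs[k]
                    vW[k] = beta2 * vW[k] + (1 - beta2) * gWs[k] ** 2
                    Ws[k] -= lr_t * mW[k] / (np.sqrt(vW[k]) + eps)
                    mb[k] = beta1 * mb[k] + (1 - beta1) * gbs[k]
                    vb[k] = beta2 * vb[k] + (1 - beta2) * gbs[k] ** 2
                    bs[k] -= lr_t * mb[k] / (np.sqrt(vb[k]) + eps)
            train_loss = ep_loss / n
            history["train_loss"].append(train_loss)

            if have_val:
                val_out, _ = self._forward(X_val, Ws, bs, rng=None)
                val_loss = float(((val_out - y_val) ** 2).sum() / X_val.shape[0])
            else:
                val_loss = train_loss
            history["val_loss"].append(val_loss)

            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = ([W.copy() for W in Ws], [b.copy() for b in bs])
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        if best_weights is not None:
            Ws, bs = best_weights
        self.weights_ = Ws
        self.biases_ = bs
        self.history_ = history
        self.n_features_in_ = d
        self.n_outputs_ = M
        self.best_val_loss_ = best_val if have_val else None
        return self

    # -------------------------------------------------------------- predict

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("ExpressionRegressor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected (n, {self.n_features_in_}) embeddings, got {X.shape}"
            )
        X = (X - self.x_mean_) / self.x_scale_
        out, _ = self._forward(X, self.weights_, self.biases_, rng=None)
        return out

    def linear_approximation(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Least-squares linear map (W, b) best explaining predict(X) from X.

        For a linear architecture this returns the learned weights exactly;
        for the MLP it is the head's effective linear response on the data.
        """
        X = np.asarray(X, dtype=float)
        P = self.predict(X)
        A = np.column_stack([X, np.ones(X.shape[0])])
        coef, *_ = np.linalg.lstsq(A, P, rcond=None)
        return coef[:-1], coef[-1]

    # ---------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        doc = {
            "params": self.get_params(),
            "weights": [W.tolist() for W in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "x_mean": self.x_mean_.tolist(),
            "x_scale": self.x_scale_.tolist(),
            "history": self.history_,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ExpressionRegressor":
        doc = json.loads(Path(path).read_text())
        params = doc["params"]
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
        est = cls(**params)
        est.weights_ = [np.array(W) for W in doc["weights"]]
        est.biases_ = [np.array(b) for b in doc["biases"]]
        est.x_mean_ = np.array(doc["x_mean"])
        est.x_scale_ = np.array(doc["x_scale"])
        est.history_ = doc["history"]
        est.n_features_in_ = est.weights_[0].shape[0]
        est.n_outputs_ = est.weights_[-1].shape[1]
        return est


def train_head(
    embeddings_train,
    z_train,
    embeddings_val,
    z_val,
    config: dict | None = None,
) -> tuple[ExpressionRegressor, dict]:
    """Train a regression head; thin functional wrapper over the estimator."""
    est = ExpressionRegressor(**(config or {}))
    est.fit(embeddings_train, z_train, embeddings_val, z_val)
    return est, est.history_


def predict(head: ExpressionRegressor, embeddings) -> np.ndarray:
    return head.predict(embeddings)
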