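"""Seeded feed-forward network machinery shared by the autoencoder, the
per-tranche regressors and the direct classifier.

A deliberately small, fully deterministic numpy implementation: dense layers
with rectified-linear hidden units, inverted dropout, Adam, mini-batches, and
early stopping on a caller-supplied validation metric with best-epoch weight
restoration.  Determinism contract: identical data + config + seed give
bit-identical weights on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = ["SeededMLP", "mean_per_gene_correlation"]


def mean_per_gene_correlation(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean Pearson correlation per output column; constant columns excluded.

    This is the early-stopping metric used for the expression regressors:
    the average correlation per gene between actual and predicted values
    on the validation set.
    """
    yt = y_true - y_true.mean(axis=0)
    yp = y_pred - y_pred.mean(axis=0)
    st = np.sqrt((yt**2).sum(axis=0))
    sp = np.sqrt((yp**2).sum(axis=0))
    ok = (st > 0) & (sp > 0)
    if not ok.any():
        return 0.0
    r = (yt[:, ok] * yp[:, ok]).sum(axis=0) / (st[ok] * sp[ok])
    return float(np.mean(r))


def _neg_mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return -float(np.mean((y_true - y_pred) ** 2))


@dataclass
class SeededMLP:
    """Dense network  sizes[0] -> ... -> sizes[-1]  with ReLU hidden layers.

    Parameters
    ----------
    sizes:
        Layer widths, input first.  ``(2048, 512, 2048)`` is the
        autoencoder; ``(512, 512, n_genes)`` a tranche regressor.
    out_activation:
        ``"linear"`` (regression, MSE loss) or ``"sigmoid"`` (binary
        classification, cross-entropy loss).
    dropout:
        Inverted-dropout rate applied to hidden activations during training.
    seed:
        Seeds weight initialisation, batch shuffling and dropout masks.
    """

    sizes: tuple[int, ...]
    out_activation: Literal["linear", "sigmoid"] = "linear"
    dropout: float = 0.2
    seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list, repr=False)
    biases: list[np.ndarray] = field(default_factory=list, repr=False)
    fitted: bool = False
    history: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.sizes) < 2:
            raise ValueError("network needs at least input and output layers")
        rng = np.random.default_rng(self.seed)
        self.weights, self.biases = [], []
        n_layers = len(self.sizes) - 1
        for i, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            # seeded uniform fan-in initialisation; hidden biases start
            # slightly positive so ReLU units are born alive
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            bias0 = 0.1 if i < n_layers - 1 else 0.0
            self.biases.append(np.full(fan_out, bias0))

    # ------------------------------------------------------------------ #

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; returns (activations, pre-activations, masks)."""
        acts = [x]
        pre = []
        masks = []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre.append(z)
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                if self.out_activation == "sigmoid":
                    h = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
                else:
                    h = z
            acts.append(h)
        return acts, pre, masks

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self._forward(x)[0][-1]

    def hidden(self, x: np.ndarray, layer: int = 1) -> np.ndarray:
        """Activations of a hidden layer (used by the autoencoder's encoder)."""
        x = np.asarray(x, dtype=float)
        return self._forward(x)[0][layer]

    # ------------------------------------------------------------------ #

    def _grads(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        acts, pre, masks = self._forward(x, rng=rng)
        n = x.shape[0]
        # MSE with linear output and BCE with sigmoid output share the same
        # output delta (prediction - target) up to the 2/n vs 1/n factor.
        if self.out_activation == "sigmoid":
            delta = (acts[-1] - y) / n
        else:
            delta = 2.0 * (acts[-1] - y) / n
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            gw[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (pre[i - 1] > 0)
        return gw, gb

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        *,
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 500,
        patience: int = 50,
        metric: Callable[[np.ndarray, np.ndarray], float] | None = None,
    ) -> "SeededMLP":
        """Adam training with early stopping on a validation metric.

        Stops after ``max_epochs`` or when the metric has not improved for
        ``patience`` consecutive epochs; the best-epoch weights are restored.
        ``metric`` is maximised (default: negative validation MSE).
        """
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        x_val = np.asarray(x_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if x_val.shape[0] == 0:
            raise ValueError("validation set must be non-empty")
        if metric is None:
            metric = _neg_mse

        rng = np.random.default_rng(self.seed + 1)
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_metric = -np.inf
        best_state = None
        stale = 0
        trace: list[float] = []
        n = x_train.shape[0]

        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                gw, gb = self._grads(x_train[idx], y_train[idx], rng)
                t += 1
                for i in range(len(self.weights)):
                    for p, g, m, v in (
                        (self.weights[i], gw[i], m_w[i], v_w[i]),
                        (self.biases[i], gb[i], m_b[i], v_b[i]),
                    ):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        mhat = m / (1 - beta1**t)
                        vhat = v / (1 - beta2**t)
                        p -= learning_rate * mhat / (np.sqrt(vhat) + eps)

            val_metric = metric(y_val, self.predict(x_val))
            trace.append(val_metric)
            if val_metric > best_metric:
                best_metric = val_metric
                best_state = (
                    [w.copy() for w in self.weights],
                    [b.copy() for b in self.biases],
                )
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break

        if best_state is not None:
            self.weights, self.biases = best_state
        self.fitted = True
        self.history = {
            "val_metric_trace": trace,
            "best_val_metric": best_metric,
            "epochs_run": len(trace),
        }
        return self
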