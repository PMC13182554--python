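"""Consistent-rank-logits (CORAL) ordinal classifier.

A small multilayer perceptron whose output layer shares a single weight
vector across the K-1 cumulative binary tasks P(y > k | x); each task gets
its own bias. The biases are parameterized as

    b_0 = b,   b_k = b - sum_{j<k} softplus(delta_j)

so b_0 >= b_1 >= ... >= b_{K-2} holds identically, which makes the cumulative
probabilities sigmoid(w.h(x) + b_k) non-increasing in k for *every* input —
rank consistency by construction, not as an outcome of optimization.

Training minimizes the sample- and class-weighted sum of binary
cross-entropies over the cumulative tasks with full-batch Adam under a fixed
seed, so fits are reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class CoralClassifier(BaseEstimator, ClassifierMixin):
    """Rank-consistent ordinal MLP over K ordered classes.

    Parameters
    ----------
    hidden_layer_size : width of the single ReLU hidden layer.
    n_epochs, learning_rate, l2 : full-batch Adam schedule and ridge penalty.
    class_weight : None or "balanced" (w_c = n / (K * n_c)).
    random_state : seed for weight initialization; fits are deterministic.
    """

    def __init__(
        self,
        hidden_layer_size: int = 32,
        n_epochs: int = 600,
        learning_rate: float = 0.02,
        l2: float = 1e-4,
        class_weight: str | None = None,
        random_state: int = 0,
    ):
        self.hidden_layer_size = hidden_layer_size
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.l2 = l2
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("CORAL needs at least two ordered classes")
        n, d = X.shape
        h = self.hidden_layer_size

        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=k)
            w = w * (n / (k * counts))[y_idx]
        w = w / w.mean()

        # targets for the K-1 cumulative tasks: t[i, j] = 1{y_i > j}
        t = (y_idx[:, None] > np.arange(k - 1)[None, :]).astype(float)

        rng = np.random.Generator(np.random.PCG64(self.random_state))
        params = {
            "W1": rng.normal(0, np.sqrt(2.0 / d), size=(d, h)),
            "b1": np.zeros(h),
            "w2": rng.normal(0, np.sqrt(1.0 / h), size=h),
            "bias": np.zeros(1),
            "delta": np.zeros(k - 2) if k > 2 else np.zeros(0),
        }
        m = {p: np.zeros_like(v) for p, v in params.items()}
        v = {p: np.zeros_like(val) for p, val in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        for step in range(1, self.n_epochs + 1):
            a1 = X @ params["W1"] + params["b1"]
            hid = np.maximum(a1, 0.0)
            g = hid @ params["w2"]
            biases = params["bias"][0] - np.concatenate([[0.0], np.cumsum(_softplus(params["delta"]))])
            z = g[:, None] + biases[None, :]
            p = _sigmoid(z)

            dz = (p - t) * w[:, None] / n  # (n, k-1)
            dg = dz.sum(axis=1)
            grads = {
                "bias": np.array([dz.sum()]),
                "w2": hid.T @ dg + self.l2 * params["w2"],
            }
            if len(params["delta"]):
                # b_j depends on delta_{0..j-1}: d b_j / d delta_m = -sigmoid(delta_m), m < j
                per_task = dz.sum(axis=0)  # (k-1,)
                tail = np.cumsum(per_task[::-1])[::-1]  # sum over tasks j >= m+1
                grads["delta"] = -_sigmoid(params["delta"]) * tail[1:]
            else:
                grads["delta"] = np.zeros(0)
            dh = np.outer(dg, params["w2"])
            dh[a1 <= 0] = 0.0
            grads["W1"] = X.T @ dh + self.l2 * params["W1"]
            grads["b1"] = dh.sum(axis=0)

            lr_t = self.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for key in params:
                m[key] = beta1 * m[key] + (1 - beta1) * grads[key]
                v[key] = beta2 * v[key] + (1 - beta2) * grads[key] ** 2
                params[key] -= lr_t * m[key] / (np.sqrt(v[key]) + eps)

        self.coef_hidden_ = params["W1"]
        self.intercept_hidden_ = params["b1"]
        self.coef_output_ = params["w2"]
        self.bias_ = float(params["bias"][0])
        self.delta_ = params["delta"]
        self.n_features_in_ = d
        return self

    def _cumulative_logits(self, X) -> np.ndarray:
        hid = np.maximum(X @ self.coef_hidden_ + self.intercept_hidden_, 0.0)
        g = hid @ self.coef_output_
        biases = self.bias_ - np.concatenate([[0.0], np.cumsum(_softplus(self.delta_))])
        return g[:, None] + biases[None, :]

    def predict_cumulative_proba(self, X) -> np.ndarray:
        """P(y > k | x) for k = 0..K-2; non-increasing in k for every row."""
        check_is_fitted(self, "coef_output_")
        X = check_array(X)
        return _sigmoid(self._cumulative_logits(X))

    def predict(self, X) -> np.ndarray:
        """Predicted class = number of cumulative probabilities above 1/2."""
        cum = self.predict_cumulative_proba(X)
        return self.classes_[(cum > 0.5).sum(axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities by differencing cumulative probabilities.

        Adjacent differences are clipped at zero and renormalized; with
        rank-consistent cumulative probabilities the clipping is a no-op.
        """
        cum = self.predict_cumulative_proba(X)
        padded = np.hstack([np.ones((len(cum), 1)), cum, np.zeros((len(cum), 1))])
        probs = np.clip(padded[:, :-1] - padded[:, 1:], 0.0, None)
        return probs / probs.sum(axis=1, keepdims=True)
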