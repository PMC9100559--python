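"""A small fully connected network with inverted dropout, written on numpy.

Architecture used throughout: three ReLU hidden layers (100, 60, 20
units), dropout rate 0.1 on the hidden activations, and either a softmax
classification head trained with cross-entropy or a single linear
regression head trained with squared error against ordinal class
indices. Training uses Adam with early stopping on validation loss; the
parameters from the best-validation epoch are restored. Keeping dropout
active at prediction time yields Monte-Carlo dropout samples.

At the problem sizes this package targets (a few thousand species, a few
dozen features) a vectorized numpy implementation trains in seconds and
keeps every arithmetic step inspectable and exactly seedable.
"""

from __future__ import annotations

import numpy as np


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Multilayer perceptron with ReLU hiddens and dropout.

    mode='classifier' -> softmax over n_out classes, cross-entropy loss;
    mode='regression' -> single linear output, mean squared error.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden=(100, 60, 20),
        mode: str = "classifier",
        dropout_rate: float = 0.1,
        seed: int = 0,
    ):
        if mode not in ("classifier", "regression"):
            raise ValueError(f"unknown mode {mode!r}")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.mode = mode
        self.dropout_rate = float(dropout_rate)
        self.n_in = int(n_in)
        self.n_out = int(n_out) if mode == "classifier" else 1
        sizes = [self.n_in, *hidden, self.n_out]
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            self.biases.append(np.zeros(b))

    # -- forward -------------------------------------------------------

    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward pass; with a dropout RNG, hidden activations are dropped
        (inverted dropout). Returns (output, hidden activations, masks)."""
        h = np.asarray(X, dtype=float)
        acts = [h]
        masks = []
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
            if dropout_rng is not None and self.dropout_rate > 0.0:
                mask = (dropout_rng.random(h.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic class probabilities (dropout off). Classifier only."""
        if self.mode != "classifier":
            raise ValueError("predict_proba is only defined for the classifier head")
        out, _, _ = self._forward(X)
        return _softmax(out)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Deterministic regression scores (dropout off)."""
        if self.mode != "regression":
            raise ValueError("predict_score is only defined for the regression head")
        out, _, _ = self._forward(X)
        return out[:, 0]

    def stochastic_forward(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One MC-dropout pass: probabilities (classifier) or scores (regression)."""
        if self.dropout_rate <= 0.0:
            raise ValueError("MC dropout needs dropout_rate > 0")
        out, _, _ = self._forward(X, dropout_rng=rng)
        return _softmax(out) if self.mode == "classifier" else out[:, 0]

    # -- loss ----------------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        out, _, _ = self._forward(X)
        if self.mode == "classifier":
            p = _softmax(out)
            return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))
        return float(np.mean((out[:, 0] - y) ** 2))

    # -- training ------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 1000,
        patience: int = 10,
        seed: int = 0,
    ) -> dict:
        """Adam + early stopping on validation loss.

        Training halts once the validation loss has not improved for
        ``patience`` consecutive epochs; the best-epoch parameters are
        restored. Returns a small history dict.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X_val is None or len(X_val) == 0:
            raise ValueError("early stopping requires a non-empty validation set")
        rng = np.random.default_rng(seed)
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = 0
        bad_epochs = 0
        history = {"val_loss": []}

        n = len(X)
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                grads = self._gradients(X[idx], y[idx], rng)
                t += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_loss = self.loss(X_val, y_val)
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_params = [p.copy() for p in params]
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
        k = len(self.weights)
        self.weights = best_params[:k]
        self.biases = best_params[k:]
        history["best_epoch"] = best_epoch
        history["best_val_loss"] = best_loss
        return history

    def _gradients(self, Xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator):
        out, acts, masks = self._forward(Xb, dropout_rng=rng)
        nb = len(Xb)
        if self.mode == "classifier":
            p = _softmax(out)
            delta = p
            delta[np.arange(nb), yb] -= 1.0
            delta /= nb
        else:
            delta = (2.0 / nb) * (out - np.asarray(yb, dtype=float)[:, None])

        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_w + grads_b

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "dropout_rate": self.dropout_rate,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls.__new__(cls)
        net.mode = d["mode"]
        net.dropout_rate = d["dropout_rate"]
        net.n_in = d["n_in"]
        net.n_out = d["n_out"]
        net.weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return net
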