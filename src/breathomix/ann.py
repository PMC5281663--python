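"""Small feedforward neural network with tanh output in [-1, 1].

One hidden layer, tanh activations on hidden and output, mean-squared-error
loss against -1/+1 labels, deterministic full-batch gradient descent.  The
bounded output makes 0.00 the natural decision threshold.  Gradients are
computed analytically and are exposed for finite-difference verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["MLPModel", "Hyperparams", "train_mlp", "predict", "loss_and_grad"]


@dataclass(frozen=True)
class Hyperparams:
    hidden: int = 4
    learning_rate: float = 0.01
    epochs: int = 2000
    init_scale: float = 0.5


@dataclass
class MLPModel:
    """Weights of a k -> h -> 1 tanh network plus training metadata."""

    w1: np.ndarray  # (k, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h, 1)
    b2: np.ndarray  # (1,)
    seed: int
    hyperparams: Hyperparams
    final_loss: float = float("nan")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_sizes": [self.w1.shape[0], self.w1.shape[1], 1],
                "w1": self.w1.ravel().tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.ravel().tolist(),
                "b2": self.b2.tolist(),
                "seed": self.seed,
                "hyperparams": {
                    "hidden": self.hyperparams.hidden,
                    "learning_rate": self.hyperparams.learning_rate,
                    "epochs": self.hyperparams.epochs,
                    "init_scale": self.hyperparams.init_scale,
                },
                "final_loss": self.final_loss,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        k, h, _ = d["layer_sizes"]
        hp = Hyperparams(**d["hyperparams"])
        return cls(
            w1=np.array(d["w1"]).reshape(k, h),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]).reshape(h, 1),
            b2=np.array(d["b2"]),
            seed=d["seed"],
            hyperparams=hp,
            final_loss=d["final_loss"],
        )


def _forward(params, X):
    w1, b1, w2, b2 = params
    hidden = np.tanh(X @ w1 + b1)
    out = np.tanh(hidden @ w2 + b2)
    return hidden, out


def loss_and_grad(params, X: np.ndarray, y: np.ndarray):
    """Mean squared error over samples and its analytic gradient.

    ``params`` is the tuple (w1, b1, w2, b2); ``y`` holds -1/+1 labels.
    Returns (loss, (dw1, db1, dw2, db2)).
    """
    w1, b1, w2, b2 = params
    n = X.shape[0]
    hidden, out = _forward(params, X)
    resid = out[:, 0] - y  # (n,)
    loss = float(np.mean(resid**2))

    # d loss / d out = 2 resid / n ; tanh' = 1 - tanh^2
    d_out = (2.0 * resid / n)[:, None] * (1.0 - out**2)  # (n, 1)
    dw2 = hidden.T @ d_out
    db2 = d_out.sum(axis=0)
    d_hidden = (d_out @ w2.T) * (1.0 - hidden**2)  # (n, h)
    dw1 = X.T @ d_hidden
    db1 = d_hidden.sum(axis=0)
    return loss, (dw1, db1, dw2, db2)


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    hyperparams: Hyperparams = Hyperparams(),
    seed: int = 0,
) -> MLPModel:
    """Train by full-batch gradient descent; deterministic given
    (data order, seed, hyperparams).

    Labels must be -1/+1 with both classes present.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, k) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be coded -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    k, h = X.shape[1], hyperparams.hidden
    rng = np.random.default_rng(seed)
    scale = hyperparams.init_scale
    w1 = rng.uniform(-scale, scale, size=(k, h)) / np.sqrt(k)
    b1 = np.zeros(h)
    w2 = rng.uniform(-scale, scale, size=(h, 1)) / np.sqrt(h)
    b2 = np.zeros(1)
    params = [w1, b1, w2, b2]
    lr = hyperparams.learning_rate
    loss = float("nan")
    for _ in range(hyperparams.epochs):
        loss, grads = loss_and_grad(tuple(params), X, y)
        for p, g in zip(params, grads):
            p -= lr * g
    loss, _ = loss_and_grad(tuple(params), X, y)
    return MLPModel(
        w1=params[0], b1=params[1], w2=params[2], b2=params[3],
        seed=seed, hyperparams=hyperparams, final_loss=loss,
    )


def predict(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Forward pass; returns predictive values in [-1, 1].

    Accepts a single feature vector (returns a scalar array of shape ())
    or an (n, k) matrix (returns shape (n,)).
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"feature length {X.shape[1]} != model input size {model.n_inputs}")
    _, out = _forward((model.w1, model.b1, model.w2, model.b2), X)
    vals = out[:, 0]
    return vals[0] if single else vals
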