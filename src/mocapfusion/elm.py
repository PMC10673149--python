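"""Extreme learning machine (ELM) regression.

A single hidden layer whose input weights and biases are drawn once at
random and never trained; only the output weights are fitted, by a
Moore-Penrose pseudoinverse least-squares solve of the hidden activation
matrix against the targets.  Used twice in the fusion pipeline: ELM 1 maps
IMU-derived joint positions to vision-derived ones, ELM 2 maps ELM 1's
output to the residual correction applied during vision outages.

Inputs are z-scored with statistics frozen at training time, so the
sigmoid hidden layer is not saturated by metre-scale coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ELMModel", "elm_train", "elm_predict", "save_elm", "load_elm"]

def _sigmoid(a):
    # clip keeps exp() in range; sigmoid saturates well before +-500 anyway
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500.0, 500.0)))


_ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
}


@dataclass(frozen=True)
class ELMModel:
    """Fitted ELM: random hidden layer plus least-squares output weights."""

    hidden_weights: np.ndarray  # (p, d), drawn uniform(-1, 1)
    biases: np.ndarray  # (d,), drawn uniform(-1, 1)
    output_weights: np.ndarray  # (d, q), pseudoinverse solve
    x_mean: np.ndarray  # (p,) training-input standardisation
    x_std: np.ndarray  # (p,)
    activation: str = "sigmoid"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(_ACTIVATIONS)}"
            )
        if not np.all(np.isfinite(self.output_weights)):
            raise ValueError("non-finite output weights")

    @property
    def hidden_size(self) -> int:
        return self.biases.size

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[0]


def _hidden(model_or_parts, X: np.ndarray) -> np.ndarray:
    W, b, x_mean, x_std, act = model_or_parts
    Xs = (X - x_mean) / x_std
    return _ACTIVATIONS[act](Xs @ W + b)


def elm_train(
    X,
    Y,
    hidden_size: int = 100,
    seed: int | None = 0,
    activation: str = "sigmoid",
) -> ELMModel:
    """Fit an ELM regressor.

    Hidden weights and biases are drawn from a seeded uniform(-1, 1)
    (numpy PCG64 generator, so the same seed reproduces the model bit for
    bit); output weights solve the hidden matrix against ``Y`` by
    pseudoinverse.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite training data")
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(p, hidden_size))
    b = rng.uniform(-1.0, 1.0, size=hidden_size)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std = np.where(x_std < 1e-12, 1.0, x_std)

    F = _hidden((W, b, x_mean, x_std, activation), X)
    beta = np.linalg.pinv(F) @ Y
    return ELMModel(W, b, beta, x_mean, x_std, activation, seed)


def elm_predict(model: ELMModel, X) -> np.ndarray:
    """Evaluate the fitted network rowwise on ``X`` (shape (s, p) or (p,))."""
    X = np.asarray(X, float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} features; model was trained with {model.n_inputs}"
        )
    F = _hidden(
        (model.hidden_weights, model.biases, model.x_mean, model.x_std, model.activation),
        X,
    )
    Y = F @ model.output_weights
    return Y[0] if single else Y


def save_elm(model: ELMModel, path) -> None:
    """Serialise weights, normalisation, activation and seed to JSON."""
    Path(path).write_text(json.dumps(elm_to_dict(model)))


def load_elm(path) -> ELMModel:
    return elm_from_dict(json.loads(Path(path).read_text()))


def elm_to_dict(model: ELMModel) -> dict:
    return {
        "hidden_weights": model.hidden_weights.tolist(),
        "biases": model.biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "activation": model.activation,
        "seed": model.seed,
    }


def elm_from_dict(d: dict) -> ELMModel:
    return ELMModel(
        np.asarray(d["hidden_weights"], float),
        np.asarray(d["biases"], float),
        np.asarray(d["output_weights"], float),
        np.asarray(d["x_mean"], float),
        np.asarray(d["x_std"], float),
        d.get("activation", "sigmoid"),
        d.get("seed"),
    )
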