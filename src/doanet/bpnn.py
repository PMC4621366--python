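"""From-scratch backpropagation network for the consciousness index.

Architecture: 7 inputs -> 10 log-sigmoid hidden units -> 1 log-sigmoid
output, trained by stochastic (per-sample) gradient descent on the
squared error E = 1/2 (y - t)^2 with a momentum term,

    dw(k) = -eta * dE/dw + alpha * dw(k-1),

eta = 0.005 and alpha = 0.15 by default, for 10,000 epochs with the row
order reshuffled each epoch.  Inputs are expected min-max normalized to
[0, 1]; the target is the clinician index divided by 100 and the
network output is mapped back by multiplying by 100.

Everything here is deliberately explicit ndarray arithmetic: the
training rule itself is the method under study, so no optimizer library
stands behind it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import INPUT_COLUMNS, TARGET_COLUMN, NormBounds, apply_normalizer

__all__ = [
    "NetworkConfig",
    "NetworkModel",
    "init_model",
    "forward",
    "gradients",
    "backprop_step",
    "train",
    "predict_index",
    "model_to_json",
    "model_from_json",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe log-sigmoid
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the index network."""

    n_inputs: int = 7
    n_hidden: int = 10
    n_outputs: int = 1
    learning_rate: float = 0.005
    momentum: float = 0.15
    epochs: int = 10_000
    init_scale: float = 0.5  # weights drawn uniform on [-init_scale, init_scale]
    seed: int = 0
    batch: bool = False  # full-batch updates instead of per-sample
    patience: int | None = None  # optional early stop on epoch MSE; off by default

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class NetworkModel:
    """Weights, biases and training metadata of one fitted network."""

    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)
    config: NetworkConfig
    norm_bounds: NormBounds | None = None
    training_mse_history: list[float] = field(default_factory=list)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            w1=self.w1.copy(),
            b1=self.b1.copy(),
            w2=self.w2.copy(),
            b2=self.b2.copy(),
            config=self.config,
            norm_bounds=self.norm_bounds,
            training_mse_history=list(self.training_mse_history),
        )


def init_model(config: NetworkConfig, norm_bounds: NormBounds | None = None) -> NetworkModel:
    """Seeded uniform [-init_scale, init_scale] initialization."""
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return NetworkModel(
        w1=rng.uniform(-s, s, size=(config.n_hidden, config.n_inputs)),
        b1=rng.uniform(-s, s, size=config.n_hidden),
        w2=rng.uniform(-s, s, size=(config.n_outputs, config.n_hidden)),
        b2=rng.uniform(-s, s, size=config.n_outputs),
        config=config,
        norm_bounds=norm_bounds,
    )


def _forward_parts(model: NetworkModel, x: np.ndarray) -> tuple[np.ndarray, float]:
    h = _sigmoid(model.w1 @ x + model.b1)
    y = _sigmoid(model.w2 @ h + model.b2)
    return h, float(y[0])


def forward(model: NetworkModel, input_row: np.ndarray) -> float:
    """Single forward pass; input values expected in [0, 1]."""
    x = np.asarray(input_row, dtype=float)
    if x.shape != (model.config.n_inputs,):
        raise ValueError(
            f"input length {x.shape} does not match n_inputs={model.config.n_inputs}"
        )
    return _forward_parts(model, x)[1]


def forward_batch(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over rows of ``X`` (n, n_inputs)."""
    X = np.asarray(X, dtype=float)
    h = _sigmoid(X @ model.w1.T + model.b1)
    return _sigmoid(h @ model.w2.T + model.b2)[:, 0]


def gradients(
    model: NetworkModel, x: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of E = 1/2 (y - t)^2 w.r.t. (w1, b1, w2, b2).

    Chain rule with sigma'(z) = sigma(z) (1 - sigma(z)).
    """
    x = np.asarray(x, dtype=float)
    h, y = _forward_parts(model, x)
    d2 = (y - t) * y * (1.0 - y)  # scalar: dE/dz2
    gw2 = d2 * h[None, :]
    gb2 = np.array([d2])
    d1 = d2 * model.w2[0] * h * (1.0 - h)
    gw1 = np.outer(d1, x)
    gb1 = d1
    return gw1, gb1, gw2, gb2


def backprop_step(
    model: NetworkModel,
    input_row: np.ndarray,
    target: float,
    state: dict[str, np.ndarray] | None = None,
) -> NetworkModel:
    """One momentum gradient step, updating the model in place.

    ``state`` carries the previous weight deltas between calls; pass the
    same dict across consecutive steps to make momentum effective.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must lie in [0, 1]")
    if state is None:
        state = {}
    g = gradients(model, input_row, target)
    if not all(np.all(np.isfinite(a)) for a in g):
        raise FloatingPointError("non-finite gradient encountered")
    eta, alpha = model.config.learning_rate, model.config.momentum
    for name, grad, param in zip(
        ("w1", "b1", "w2", "b2"), g, (model.w1, model.b1, model.w2, model.b2)
    ):
        prev = state.get(name, 0.0)
        delta = -eta * grad + alpha * prev
        param += delta
        state[name] = delta
    return model


def _training_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    t = table[TARGET_COLUMN].to_numpy(dtype=float)
    return X, t


def train(
    table: pd.DataFrame,
    config: NetworkConfig,
    norm_bounds: NormBounds | None = None,
) -> NetworkModel:
    """Train on a normalized feature table (inputs in [0,1], target in [0,1]).

    Online mode visits rows one at a time in an order reshuffled every
    epoch from the config seed; the recorded per-epoch MSE is the mean
    of the squared errors observed during that pass.  Batch mode
    (``config.batch``) applies the mean gradient once per epoch.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    X, t = _training_arrays(table)
    if t.min() < 0 or t.max() > 1:
        raise ValueError("targets must be scaled to [0, 1] before training")
    model = init_model(config, norm_bounds)
    rng = np.random.default_rng(config.seed + 1)
    eta, alpha = config.learning_rate, config.momentum
    w1, b1, w2, b2 = model.w1, model.b1, model.w2, model.b2
    dw1 = np.zeros_like(w1)
    db1 = np.zeros_like(b1)
    dw2 = np.zeros_like(w2)
    db2 = np.zeros_like(b2)
    n = len(t)
    history = model.training_mse_history
    best = np.inf
    stale = 0
    for _ in range(config.epochs):
        if config.batch:
            h = _sigmoid(X @ w1.T + b1)
            y = _sigmoid(h @ w2.T + b2)[:, 0]
            err = y - t
            d2 = (err * y * (1.0 - y)) / n
            gw2 = d2 @ h
            gb2 = d2.sum()
            d1 = (d2[:, None] * w2[0]) * h * (1.0 - h)
            gw1 = d1.T @ X
            gb1 = d1.sum(axis=0)
            dw1 = -eta * gw1 + alpha * dw1
            db1 = -eta * gb1 + alpha * db1
            dw2 = -eta * gw2[None, :] + alpha * dw2
            db2 = -eta * np.array([gb2]) + alpha * db2
            w1 += dw1
            b1 += db1
            w2 += dw2
            b2 += db2
            mse = float(np.mean(err**2))
        else:
            order = rng.permutation(n)
            sq = 0.0
            for i in order:
                x = X[i]
                z1 = w1 @ x + b1
                h = 1.0 / (1.0 + np.exp(-z1))
                y = 1.0 / (1.0 + np.exp(-(w2 @ h + b2)[0]))
                err = y - t[i]
                sq += err * err
                d2 = err * y * (1.0 - y)
                d1 = (d2 * w2[0]) * h * (1.0 - h)
                dw1 = -eta * np.outer(d1, x) + alpha * dw1
                db1 = -eta * d1 + alpha * db1
                dw2 = -eta * d2 * h[None, :] + alpha * dw2
                db2 = -eta * np.array([d2]) + alpha * db2
                w1 += dw1
                b1 += db1
                w2 += dw2
                b2 += db2
            mse = sq / n
        history.append(mse)
        if config.patience is not None:
            if mse < best - 1e-12:
                best, stale = mse, 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if not all(
        np.all(np.isfinite(a)) for a in (w1, b1, w2, b2)
    ):  # pragma: no cover - defensive
        raise FloatingPointError("training diverged to non-finite weights")
    return model


def predict_index(model: NetworkModel, table: pd.DataFrame) -> np.ndarray:
    """Consciousness index in (0, 100) per row of a raw feature table.

    The model's stored normalization bounds are applied first; passing a
    model without bounds requires an already-normalized table.
    """
    if model.norm_bounds is not None:
        table = apply_normalizer(table, model.norm_bounds)
    X = table[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    return 100.0 * forward_batch(model, X)


def model_to_json(model: NetworkModel, path: str | Path | None = None) -> str:
    cfg = model.config
    payload = {
        "config": {
            k: getattr(cfg, k)
            for k in (
                "n_inputs",
                "n_hidden",
                "n_outputs",
                "learning_rate",
                "momentum",
                "epochs",
                "init_scale",
                "seed",
                "batch",
                "patience",
            )
        },
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "norm_bounds": (
            {k: list(v) for k, v in model.norm_bounds.bounds.items()}
            if model.norm_bounds is not None
            else None
        ),
        "training_mse_history": model.training_mse_history,
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(text_or_path: str | Path) -> NetworkModel:
    p = Path(str(text_or_path))
    text = p.read_text() if p.exists() else str(text_or_path)
    raw = json.loads(text)
    cfg = NetworkConfig(**raw["config"])
    nb = raw.get("norm_bounds")
    return NetworkModel(
        w1=np.asarray(raw["w1"], dtype=float),
        b1=np.asarray(raw["b1"], dtype=float),
        w2=np.asarray(raw["w2"], dtype=float),
        b2=np.asarray(raw["b2"], dtype=float),
        config=cfg,
        norm_bounds=(
            NormBounds(bounds={k: (float(v[0]), float(v[1])) for k, v in nb.items()})
            if nb
            else None
        ),
        training_mse_history=list(raw.get("training_mse_history", [])),
    )
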