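"""Single-hidden-layer backpropagation network for abundance-class SDMs.

The model is a plain feed-forward network: logistic hidden layer, and by
default a single logistic output trained against the class code scaled to
[0, 1] (class/3), so the network behaves like a bounded regression on the
ordinal abundance scale and a predicted class is recovered by rounding.
A 4-output one-hot/argmax variant is available behind a config switch.

Training is full-batch gradient descent with momentum on squared error.
A random 20% holdout is carved out before training and never contributes
to gradient updates; the weights returned are those of the epoch with the
lowest holdout error, and training stops once the holdout error has not
improved for ``patience`` epochs (early stopping against overlearning).

Variable influence is read off the fitted weights by connection-weight
tracing: the signed importance of input i is the sum over hidden neurons
of (input->hidden weight) x (hidden->output weight).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NetConfig", "TrainedSDM", "train", "predict_class",
           "predict_score", "relative_weights"]

N_CLASSES = 4


@dataclass
class NetConfig:
    """Architecture and training hyper-parameters.

    ``n_hidden`` defaults follow the benchmark models: 46 hidden neurons
    for the 10-variable run (use 55 for the 19-variable disturbance run).
    The optimizer constants are free parameters of this implementation —
    the original commercial tool's internals are unpublished — chosen as
    conventional values for logistic nets of this size.
    """

    n_inputs: int
    n_hidden: int = 46
    output_mode: str = "scalar"     # "scalar" (class/3 regression) or "onehot"
    learning_rate: float = 2.0
    momentum: float = 0.9
    max_epochs: int = 20000
    patience: int = 200
    holdout_fraction: float = 0.2
    init_scale: float = 0.5         # weights ~ U(-init_scale, init_scale)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.output_mode not in ("scalar", "onehot"):
            raise ValueError("output_mode must be 'scalar' or 'onehot'")


@dataclass
class TrainedSDM:
    """Fitted network: input scaling, weights, and training history."""

    config: NetConfig
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    w1: np.ndarray                  # (n_inputs, n_hidden)
    b1: np.ndarray                  # (n_hidden,)
    w2: np.ndarray                  # (n_hidden, n_outputs)
    b2: np.ndarray                  # (n_outputs,)
    history: pd.DataFrame           # epoch, train_mse, holdout_mse
    best_epoch: int
    train_index: np.ndarray = field(repr=False)
    holdout_index: np.ndarray = field(repr=False)

    def save(self, path) -> None:
        doc = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "best_epoch": self.best_epoch,
            "train_index": self.train_index.tolist(),
            "holdout_index": self.holdout_index.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "TrainedSDM":
        doc = json.loads(Path(path).read_text())
        return cls(
            config=NetConfig(**doc["config"]),
            feature_names=doc["feature_names"],
            x_mean=np.array(doc["x_mean"]), x_sd=np.array(doc["x_sd"]),
            w1=np.array(doc["w1"]), b1=np.array(doc["b1"]),
            w2=np.array(doc["w2"]), b2=np.array(doc["b2"]),
            history=pd.DataFrame(), best_epoch=doc["best_epoch"],
            train_index=np.array(doc["train_index"], dtype=int),
            holdout_index=np.array(doc["holdout_index"], dtype=int),
        )


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _as_matrix(features, names=None):
    if isinstance(features, pd.DataFrame):
        if names is not None:
            missing = [n for n in names if n not in features.columns]
            if missing:
                raise KeyError(f"missing model input variable(s): {missing}")
            features = features[names]
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, (list(names) if names is not None else
               [f"x{i}" for i in range(X.shape[1])])


def _forward(model: TrainedSDM, X: np.ndarray):
    Z = (X - model.x_mean) / model.x_sd
    H = _logistic(Z @ model.w1 + model.b1)
    return _logistic(H @ model.w2 + model.b2)


def train(features, targets, config: NetConfig) -> TrainedSDM:
    """Fit the network to (feature table, abundance-class codes).

    Inputs are z-scored by training-set statistics; targets become
    class/3 (scalar mode) or one-hot rows (onehot mode). Fully
    deterministic given the config seed. Requires >= 10 rows and enough
    rows that both the training and holdout partitions are non-empty.
    """
    X, names = _as_matrix(features)
    y = np.asarray(targets, dtype=int)
    if X.shape[1] != config.n_inputs:
        raise ValueError(f"config expects {config.n_inputs} inputs, "
                         f"got {X.shape[1]}")
    if len(X) != len(y):
        raise ValueError("features and targets length mismatch")
    if len(X) < 10:
        raise ValueError("need at least 10 rows to fit")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if y.min() < 0 or y.max() >= N_CLASSES:
        raise ValueError("targets must be class codes 0..3")

    rng = np.random.default_rng(config.seed)
    n = len(X)
    n_hold = int(round(config.holdout_fraction * n))
    if n_hold < 1 or n - n_hold < 1:
        raise ValueError("holdout_fraction leaves an empty partition")
    perm = rng.permutation(n)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]

    x_mean = X[train_idx].mean(axis=0)
    x_sd = X[train_idx].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Zt = (X[train_idx] - x_mean) / x_sd
    Zh = (X[hold_idx] - x_mean) / x_sd

    if config.output_mode == "scalar":
        n_out = 1
        Tt = (y[train_idx] / (N_CLASSES - 1))[:, None]
        Th = (y[hold_idx] / (N_CLASSES - 1))[:, None]
    else:
        n_out = N_CLASSES
        Tt = np.eye(N_CLASSES)[y[train_idx]]
        Th = np.eye(N_CLASSES)[y[hold_idx]]

    s = config.init_scale
    w1 = rng.uniform(-s, s, (config.n_inputs, config.n_hidden))
    b1 = rng.uniform(-s, s, config.n_hidden)
    w2 = rng.uniform(-s, s, (config.n_hidden, n_out))
    b2 = rng.uniform(-s, s, n_out)
    v = [np.zeros_like(p) for p in (w1, b1, w2, b2)]

    best = {"err": np.inf, "epoch": -1, "params": None}
    hist_epoch, hist_train, hist_hold = [], [], []
    lr, mom = config.learning_rate, config.momentum
    nt = len(Zt)

    for epoch in range(config.max_epochs):
        H = _logistic(Zt @ w1 + b1)
        Y = _logistic(H @ w2 + b2)
        err = Y - Tt
        train_mse = float((err**2).mean())

        # backprop through the two logistic layers (mean squared error)
        d_out = err * Y * (1 - Y) / nt
        g_w2 = H.T @ d_out
        g_b2 = d_out.sum(axis=0)
        d_hid = (d_out @ w2.T) * H * (1 - H)
        g_w1 = Zt.T @ d_hid
        g_b1 = d_hid.sum(axis=0)

        for p, vel, g in zip((w1, b1, w2, b2), v, (g_w1, g_b1, g_w2, g_b2)):
            vel *= mom
            vel -= lr * g
            p += vel

        Yh = _logistic(_logistic(Zh @ w1 + b1) @ w2 + b2)
        hold_mse = float(((Yh - Th) ** 2).mean())
        hist_epoch.append(epoch)
        hist_train.append(train_mse)
        hist_hold.append(hold_mse)

        if hold_mse < best["err"] - 1e-12:
            best = {"err": hold_mse, "epoch": epoch,
                    "params": tuple(p.copy() for p in (w1, b1, w2, b2))}
        elif epoch - best["epoch"] >= config.patience:
            break

    w1, b1, w2, b2 = best["params"]
    history = pd.DataFrame({"epoch": hist_epoch, "train_mse": hist_train,
                            "holdout_mse": hist_hold})
    return TrainedSDM(config=config, feature_names=names,
                      x_mean=x_mean, x_sd=x_sd,
                      w1=w1, b1=b1, w2=w2, b2=b2,
                      history=history, best_epoch=best["epoch"],
                      train_index=np.sort(train_idx),
                      holdout_index=np.sort(hold_idx))


def predict_score(model: TrainedSDM, features) -> np.ndarray:
    """Continuous network output per row.

    Scalar mode: one score in [0, 1] per row (class scale / 3).
    One-hot mode: an (n, 4) matrix of class activations.
    """
    X, _ = _as_matrix(features, model.feature_names)
    if X.shape[1] != model.config.n_inputs:
        raise ValueError("feature count does not match the trained model")
    Y = _forward(model, X)
    return Y[:, 0] if model.config.output_mode == "scalar" else Y


def predict_class(model: TrainedSDM, features) -> np.ndarray:
    """Predicted abundance-class codes per row.

    Scalar mode rounds 3*score to the nearest class and clamps to [0, 3];
    one-hot mode takes the argmax activation.
    """
    score = predict_score(model, features)
    if model.config.output_mode == "scalar":
        return np.clip(np.rint(score * (N_CLASSES - 1)), 0,
                       N_CLASSES - 1).astype(np.int8)
    return score.argmax(axis=1).astype(np.int8)


def relative_weights(model: TrainedSDM, scale_to: float | None = None) -> pd.Series:
    """Signed connection-weight importance per input variable.

    importance(i) = sum_h w1[i, h] * w2[h, out]. In one-hot mode the
    output weight of each hidden neuron is collapsed to its class-score
    projection sum_k (k/3) * w2[h, k] so the sign convention matches the
    scalar mode. If ``scale_to`` is given, importances are rescaled so
    the largest magnitude equals it.
    """
    if model.config.output_mode == "scalar":
        w_out = model.w2[:, 0]
    else:
        w_out = model.w2 @ (np.arange(N_CLASSES) / (N_CLASSES - 1))
    imp = model.w1 @ w_out
    if scale_to is not None:
        peak = np.abs(imp).max()
        if peak > 0:
            imp = imp * (scale_to / peak)
    return pd.Series(imp, index=model.feature_names, name="relative_weight")
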