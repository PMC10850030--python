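"""Per-workplace neural surrogate: lagged features, split, training.

The surrogate maps 18 outdoor features to one indoor target through a
single hidden layer of 16 sigmoid units and a linear output, trained with
Adam (learning rate 1e-4, batch size 8) under early stopping on a held-out
validation split. Inputs and the target are z-scored with statistics of
the training split only. The implementation is a small self-contained
numpy network so that training is bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import MeteoSeries

#: Lags (hours) of the three lagged driver variables.
LAG_HOURS = (3, 6, 12, 24)
LAGGED_VARS = ("ta", "g", "ag")
CURRENT_VARS = ("ta", "td", "v", "p", "g", "ag")

#: Fixed column-order contract of the 18-feature matrix.
FEATURE_COLUMNS = tuple(CURRENT_VARS) + tuple(
    f"{var}_lag{h}" for var in LAGGED_VARS for h in LAG_HOURS
)


def build_feature_matrix(series: MeteoSeries) -> pd.DataFrame:
    """18-column lagged feature matrix; rows where all lags exist.

    Columns follow :data:`FEATURE_COLUMNS`: the six current variables,
    then ta, g, ag each at 3, 6, 12 and 24 hours before t.
    """
    step = series.step_hours
    if any(h % step for h in LAG_HOURS):
        raise ValueError(f"step of {step} h does not divide the lag offsets")
    df = series.data
    if len(df) * step < max(LAG_HOURS):
        raise ValueError("series shorter than the 24 h lag history")
    cols = {var: df[var] for var in CURRENT_VARS}
    for var in LAGGED_VARS:
        for h in LAG_HOURS:
            cols[f"{var}_lag{h}"] = df[var].shift(h // step)
    X = pd.DataFrame(cols, index=df.index)[list(FEATURE_COLUMNS)]
    return X.dropna()


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test row indices (80/10/10)."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.train) + len(self.val) + len(self.test)
        union = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(union)) != n:
            raise ValueError("split sets must be disjoint")


def split_dataset(
    n_rows: int, seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> DataSplit:
    """Random 80/10/10 split of row indices, reproducible per seed."""
    if n_rows < 10:
        raise ValueError("need at least 10 rows for an 80/10/10 split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_val = int(round(fractions[1] * n_rows))
    n_test = int(round(fractions[2] * n_rows))
    return DataSplit(
        train=np.sort(perm[n_val + n_test :]),
        val=np.sort(perm[:n_val]),
        test=np.sort(perm[n_val : n_val + n_test]),
        seed=seed,
    )


@dataclass
class Hyperparameters:
    hidden_units: int = 16
    batch_size: int = 8
    learning_rate: float = 1e-4
    max_epochs: int = 500
    patience: int = 20


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class SurrogateModel:
    """Trained 18-16(sigmoid)-1(linear) network with its scalers."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    workplace_id: str = ""
    target: str = "ti"
    seed: int = 0
    epochs_run: int = 0
    best_epoch: int = 0
    test_mae: float = float("nan")
    history: list[dict] = field(default_factory=list, repr=False)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Forward pass on raw (unscaled) features -> unscaled predictions."""
        Xs = (X - self.x_mean) / self.x_scale
        hidden = _sigmoid(Xs @ self.w1 + self.b1)
        return (hidden @ self.w2 + self.b2).ravel() * self.y_scale + self.y_mean

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_columns if c not in X.columns]
            if missing:
                raise ValueError(f"feature mismatch, missing columns: {missing}")
            X = X[list(self.feature_columns)].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_columns):
            raise ValueError("feature count mismatch with the trained scaler")
        return self.forward(X)

    def to_json(self, path) -> None:
        payload = {
            "architecture": [self.w1.shape[0], self.w1.shape[1], 1],
            "activation": ["sigmoid", "linear"],
            "weights": {
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2.tolist(),
            },
            "scaler": {
                "x_mean": self.x_mean.tolist(),
                "x_scale": self.x_scale.tolist(),
                "y_mean": self.y_mean,
                "y_scale": self.y_scale,
            },
            "feature_columns": list(self.feature_columns),
            "metadata": {
                "workplace_id": self.workplace_id,
                "target": self.target,
                "seed": self.seed,
                "epochs_run": self.epochs_run,
                "best_epoch": self.best_epoch,
                "test_mae": self.test_mae,
                "optimizer": "adam",
                "learning_rate": 1e-4,
                "batch_size": 8,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            payload = json.load(fh)
        w = payload["weights"]
        s = payload["scaler"]
        m = payload["metadata"]
        return cls(
            w1=np.asarray(w["w1"]),
            b1=np.asarray(w["b1"]),
            w2=np.asarray(w["w2"]),
            b2=np.asarray(w["b2"]),
            x_mean=np.asarray(s["x_mean"]),
            x_scale=np.asarray(s["x_scale"]),
            y_mean=s["y_mean"],
            y_scale=s["y_scale"],
            feature_columns=tuple(payload["feature_columns"]),
            workplace_id=m["workplace_id"],
            target=m["target"],
            seed=m["seed"],
            epochs_run=m["epochs_run"],
            best_epoch=m["best_epoch"],
            test_mae=m["test_mae"],
        )


def _mse_grads(Xs, y, params):
    w1, b1, w2, b2 = params
    hidden = _sigmoid(Xs @ w1 + b1)
    pred = hidden @ w2 + b2
    err = pred - y[:, None]
    n = len(y)
    d_out = 2.0 * err / n
    g_w2 = hidden.T @ d_out
    g_b2 = d_out.sum(axis=0)
    d_hidden = (d_out @ w2.T) * hidden * (1.0 - hidden)
    g_w1 = Xs.T @ d_hidden
    g_b1 = d_hidden.sum(axis=0)
    return [g_w1, g_b1, g_w2, g_b2]


def train_surrogate(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    split: DataSplit,
    hyper: Hyperparameters | None = None,
    seed: int = 0,
    workplace_id: str = "",
    target: str = "ti",
) -> SurrogateModel:
    """Train the surrogate; deterministic for a given seed.

    Minimizes mean squared error on the training split; stops when the
    validation loss has not improved for ``patience`` epochs and restores
    the best-validation weights.
    """
    hyper = hyper or Hyperparameters()
    feature_columns = FEATURE_COLUMNS
    if isinstance(X, pd.DataFrame):
        feature_columns = tuple(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must be aligned")
    if not np.isfinite(y).all():
        raise ValueError("non-finite target values")

    x_mean = X[split.train].mean(axis=0)
    x_scale = X[split.train].std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    y_mean = float(y[split.train].mean())
    y_scale = float(y[split.train].std())
    if y_scale < 1e-12:
        y_scale = 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    rng = np.random.default_rng(seed)
    n_in, n_hidden = X.shape[1], hyper.hidden_units
    limit1 = np.sqrt(6.0 / (n_in + n_hidden))
    limit2 = np.sqrt(6.0 / (n_hidden + 1))
    params = [
        rng.uniform(-limit1, limit1, size=(n_in, n_hidden)),
        np.zeros(n_hidden),
        rng.uniform(-limit2, limit2, size=(n_hidden, 1)),
        np.zeros(1),
    ]
    adam = _Adam(params, hyper.learning_rate)

    X_tr, y_tr = Xs[split.train], ys[split.train]
    X_val, y_val = Xs[split.val], ys[split.val]
    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = 0
    history = []
    wait = 0
    n_tr = len(X_tr)
    for epoch in range(1, hyper.max_epochs + 1):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            grads = _mse_grads(X_tr[idx], y_tr[idx], params)
            adam.step(params, grads)
        train_pred = (_sigmoid(X_tr @ params[0] + params[1]) @ params[2] + params[3]).ravel()
        train_loss = float(np.mean((train_pred - y_tr) ** 2))
        val_pred = (_sigmoid(X_val @ params[0] + params[1]) @ params[2] + params[3]).ravel()
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"divergent loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= hyper.patience:
                break

    w1, b1, w2, b2 = best_params
    model = SurrogateModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        feature_columns=feature_columns,
        workplace_id=workplace_id,
        target=target,
        seed=seed,
        epochs_run=len(history),
        best_epoch=best_epoch,
        history=history,
    )
    model.test_mae = evaluate_mae(model, X[split.test], y[split.test])
    return model


def evaluate_mae(model: SurrogateModel, X_test, y_test) -> float:
    """Mean absolute error of model predictions on a test set (K)."""
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    return float(np.mean(np.abs(model.predict(X_test) - y_test)))


def predict_series(model: SurrogateModel, series: MeteoSeries) -> pd.Series:
    """Predict the target over a meteorological series (usable rows only)."""
    X = build_feature_matrix(series)
    return pd.Series(model.predict(X), index=X.index, name=model.target)


def training_log_to_csv(model: SurrogateModel, path) -> None:
    pd.DataFrame(model.history).to_csv(path, index=False)
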