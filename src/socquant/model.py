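"""Multi-task quantile regression neural network for SOC percentiles.

A single fully-connected network (three hidden ReLU layers of 20 units by
default) maps standardized covariates — mean annual temperature, total annual
precipitation, elevation and a one-hot land-cover encoding — to five output
heads, one per conditional percentile (25, 50, 75, 90, 95). Each head is
trained with the pinball (quantile) loss

    L_tau = (1/n) Σ max{ tau·(y−ŷ), (tau−1)·(y−ŷ) }

whose minimizer is the conditional tau-quantile; the total loss is the sum of
the five head losses, so the shared trunk learns a representation useful for
the whole conditional distribution. The 25th and 95th heads act purely as
co-trained regularizers — downstream accounting only consumes q50/q75/q90.

The network, backpropagation and the Adam optimizer are implemented directly
on numpy arrays; the problem is small (tens of thousands of rows, a few
covariates) and a seeded numpy implementation keeps the whole train/predict
path deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import LANDCOVER_CLASSES

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ("mat", "tap", "elevation")
DEFAULT_PERCENTILES = (0.25, 0.50, 0.75, 0.90, 0.95)


def pinball_loss(y, yhat, tau: float):
    """Pinball loss max{tau·e, (tau−1)·e}, e = y − ŷ; scalar inputs give a
    scalar, arrays give the batch mean."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    e = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    loss = np.maximum(tau * e, (tau - 1.0) * e)
    return float(np.mean(loss))


def total_loss(y, yhat_heads, percentiles=DEFAULT_PERCENTILES):
    """Sum of the per-head batch-mean pinball losses.

    ``yhat_heads``: array (n, n_heads) or mapping percentile → predictions.
    """
    if isinstance(yhat_heads, dict):
        cols = [yhat_heads[tau] for tau in percentiles]
        yhat_heads = np.column_stack(cols)
    yhat_heads = np.atleast_2d(np.asarray(yhat_heads, dtype=float))
    if yhat_heads.shape[1] != len(percentiles):
        raise ValueError("one prediction column per percentile head required")
    return sum(
        pinball_loss(y, yhat_heads[:, k], tau) for k, tau in enumerate(percentiles)
    )


@dataclass(frozen=True)
class ModelSpec:
    hidden_layers: tuple = (20, 20, 20)
    percentiles: tuple = DEFAULT_PERCENTILES

    def __post_init__(self):
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        p = self.percentiles
        if not all(0 < a < 1 for a in p) or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("percentiles must be strictly increasing in (0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings. ``lr_final_fraction`` < 1 applies an exponential
    learning-rate decay across epochs down to that fraction of the initial
    rate (1.0 keeps the rate constant, the published setting)."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.001
    test_fraction: float = 0.05
    seed: int = 42
    lr_final_fraction: float = 1.0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0.0 < self.lr_final_fraction <= 1.0:
            raise ValueError("lr_final_fraction must lie in (0, 1]")


#: optimization settings used for the package's synthetic recovery/coverage
#: studies: longer schedule with learning-rate decay for a tight final fit
SYNTHETIC_STUDY_TRAINING = TrainingConfig(
    epochs=200, batch_size=128, learning_rate=0.003, lr_final_fraction=0.03
)


class Standardizer:
    """Per-covariate z-scoring + land-cover one-hot, fitted on training rows only."""

    def __init__(self, continuous=CONTINUOUS_COVARIATES, landcover_col="landcover"):
        self.continuous = tuple(continuous)
        self.landcover_col = landcover_col
        self.means_ = None
        self.sds_ = None

    def fit(self, frame: pd.DataFrame) -> "Standardizer":
        X = frame[list(self.continuous)].to_numpy(dtype=float)
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0)
        if np.any(self.sds_ <= 0):
            raise ValueError("a continuous covariate has zero variance in training data")
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("standardizer not fitted")
        X = (frame[list(self.continuous)].to_numpy(dtype=float) - self.means_) / self.sds_
        if self.landcover_col is not None:
            lc = frame[self.landcover_col].to_numpy()
            onehot = np.column_stack([(lc == c).astype(float) for c in LANDCOVER_CLASSES])
            X = np.column_stack([X, onehot])
        return X

    @property
    def feature_names(self):
        names = list(self.continuous)
        if self.landcover_col is not None:
            names += [f"landcover:{c}" for c in LANDCOVER_CLASSES]
        return names

    def to_dict(self):
        return {
            "continuous": list(self.continuous),
            "landcover_col": self.landcover_col,
            "means": list(map(float, self.means_)),
            "sds": list(map(float, self.sds_)),
        }

    @classmethod
    def from_dict(cls, d):
        s = cls(d["continuous"], d["landcover_col"])
        s.means_ = np.asarray(d["means"], dtype=float)
        s.sds_ = np.asarray(d["sds"], dtype=float)
        return s


class _MLP:
    """Plain numpy ReLU network with one linear unit per percentile head."""

    def __init__(self, n_in: int, hidden, n_out: int, rng: np.random.Generator):
        sizes = [n_in, *hidden, n_out]
        self.W = [
            rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def forward(self, X, keep_cache=False):
        h = X
        cache = [h]
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            cache.append(h)
        out = h @ self.W[-1] + self.b[-1]
        return (out, cache) if keep_cache else out

    def backward(self, cache, dout):
        """Gradients of the loss given d(loss)/d(output)."""
        grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
        delta = dout
        for layer in range(len(self.W) - 1, -1, -1):
            grads_W[layer] = cache[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (cache[layer] > 0)
        return grads_W, grads_b

    @property
    def params(self):
        return self.W + self.b

    def to_arrays(self):
        out = {}
        for i, W in enumerate(self.W):
            out[f"W{i}"] = W
        for i, b in enumerate(self.b):
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_arrays(cls, arrays):
        obj = cls.__new__(cls)
        n = len([k for k in arrays if k.startswith("W")])
        obj.W = [np.asarray(arrays[f"W{i}"]) for i in range(n)]
        obj.b = [np.asarray(arrays[f"b{i}"]) for i in range(n)]
        return obj


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def split_data(samples: pd.DataFrame, test_fraction: float = 0.05, seed: int = 42,
               n_bootstrap: int = 1):
    """Hold out a test set, then bootstrap the pool into train/validation.

    The test set is a simple random sample of round(test_fraction·n) rows;
    each bootstrap resample draws the pool with replacement as training and
    uses the out-of-bag rows (≈36.8% of the pool in expectation) as
    validation.

    Returns (pool_index, test_index, [(train_index, val_index), ...]) as
    positional index arrays into ``samples``.
    """
    n = len(samples)
    if n < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * n))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    pool_idx = np.sort(perm[n_test:])
    resamples = []
    for _ in range(n_bootstrap):
        train = rng.choice(pool_idx, size=len(pool_idx), replace=True)
        oob = np.setdiff1d(pool_idx, train)
        resamples.append((train, oob))
    return pool_idx, test_idx, resamples


@dataclass
class TrainedQuantileModel:
    net: _MLP
    standardizer: Standardizer
    spec: ModelSpec
    loss_history: list = field(default_factory=list)
    crossing_count: int = 0

    def predict_rows(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Quantile predictions for covariate rows, non-crossing and floored at 0.

        Returns a frame with one column per percentile (q25 … q95).
        """
        X = self.standardizer.transform(frame)
        raw = self.net.forward(X)
        crossings = int(np.sum(np.any(np.diff(raw, axis=1) < 0, axis=1)))
        if crossings:
            self.crossing_count += crossings
            logger.debug("sorted %d crossing quantile sets", crossings)
        q = np.maximum(np.sort(raw, axis=1), 0.0)
        cols = {f"q{int(round(tau * 100))}": q[:, k]
                for k, tau in enumerate(self.spec.percentiles)}
        return pd.DataFrame(cols, index=frame.index)

    def predict_grid(self, grid):
        """Quantile predictions over an xarray covariate stack.

        Returns a Dataset with one variable per percentile on the grid's dims.
        """
        import xarray as xr

        classes = grid.attrs.get("landcover_classes", list(LANDCOVER_CLASSES))
        if isinstance(classes, str):
            classes = classes.split(",")
        frame = pd.DataFrame(
            {
                "mat": grid["mat"].values.ravel(),
                "tap": grid["tap"].values.ravel(),
                "elevation": grid["elevation"].values.ravel(),
                "landcover": np.asarray(classes)[grid["landcover"].values.ravel()],
            }
        )
        q = self.predict_rows(frame)
        shape = grid["mat"].shape
        data = {col: (grid["mat"].dims, q[col].to_numpy().reshape(shape)) for col in q}
        return xr.Dataset(data, coords=grid.coords)

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.to_arrays())
        meta = {
            "standardizer": self.standardizer.to_dict(),
            "hidden_layers": list(self.spec.hidden_layers),
            "percentiles": list(self.spec.percentiles),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        with np.load(directory / "weights.npz") as npz:
            net = _MLP.from_arrays(dict(npz))
        return cls(
            net=net,
            standardizer=Standardizer.from_dict(meta["standardizer"]),
            spec=ModelSpec(tuple(meta["hidden_layers"]), tuple(meta["percentiles"])),
        )


def _pinball_grad(y_col, yhat, percentiles):
    """d(total pinball)/d(yhat): -tau below the data point, (1-tau) above."""
    taus = np.asarray(percentiles)
    e = y_col - yhat  # (n, heads)
    return np.where(e > 0, -taus, 1.0 - taus) / len(y_col)


def train(
    samples: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    config: TrainingConfig = TrainingConfig(),
    target_col: str = "soc_pct",
    standardizer: Standardizer | None = None,
) -> TrainedQuantileModel:
    """Train the multi-task quantile network on harmonized samples.

    The standardizer is fitted on the provided rows (pass the training split,
    not the full table, to keep the test set untouched). Deterministic for a
    fixed (samples, spec, config).
    """
    if len(samples) == 0:
        raise ValueError("empty training set")
    std = standardizer or Standardizer()
    if std.means_ is None:
        std.fit(samples)
    X = std.transform(samples)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates in training data")
    y = samples[target_col].to_numpy(dtype=float)

    rng = np.random.default_rng(config.seed)
    net = _MLP(X.shape[1], spec.hidden_layers, len(spec.percentiles), rng)
    opt = _Adam(net.params, config.learning_rate)
    y_col = y[:, None]
    n = len(y)
    history = []
    for epoch in range(config.epochs):
        if config.lr_final_fraction < 1.0 and config.epochs > 1:
            opt.lr = config.learning_rate * config.lr_final_fraction ** (
                epoch / (config.epochs - 1)
            )
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out, cache = net.forward(X[idx], keep_cache=True)
            e = y_col[idx] - out
            taus = np.asarray(spec.percentiles)
            epoch_loss += np.maximum(taus * e, (taus - 1.0) * e).mean(axis=0).sum() * len(idx)
            dout = _pinball_grad(y_col[idx], out, spec.percentiles)
            gW, gb = net.backward(cache, dout)
            opt.step(net.params, gW + gb)
        history.append(epoch_loss / n)
    return TrainedQuantileModel(net=net, standardizer=std, spec=spec,
                                loss_history=history)


def train_per_landcover(samples, spec=ModelSpec(), config=TrainingConfig(),
                        target_col="soc_pct"):
    """One independent model per land-cover group (no land-cover covariate)."""
    models = {}
    for k, lc in enumerate(LANDCOVER_CLASSES):
        sub = samples[samples["landcover"] == lc]
        if len(sub) == 0:
            raise ValueError(f"no samples for land cover {lc!r}")
        std = Standardizer(landcover_col=None).fit(sub)
        sub_config = TrainingConfig(
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            test_fraction=config.test_fraction, seed=config.seed + k,
        )
        models[lc] = train(sub, spec, sub_config, target_col, standardizer=std)
    return models


def rmse_q50(model: TrainedQuantileModel, test: pd.DataFrame,
             target_col: str = "soc_pct") -> float:
    """Root mean squared error of the median head on a held-out set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict_rows(test)["q50"].to_numpy()
    resid = test[target_col].to_numpy(dtype=float) - pred
    return float(np.sqrt(np.mean(resid**2)))


def select_best(models_with_val, samples, target_col="soc_pct"):
    """Pick the bootstrap model with the lowest out-of-bag total loss
    (ties broken by position, i.e. seed order)."""
    best, best_loss = None, np.inf
    for model, val_idx in models_with_val:
        val = samples.iloc[val_idx]
        q = model.predict_rows(val).to_numpy()
        loss = total_loss(val[target_col].to_numpy(), q, model.spec.percentiles)
        if loss < best_loss:
            best, best_loss = model, loss
    return best, best_loss
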