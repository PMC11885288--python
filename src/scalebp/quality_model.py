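"""Stacked time-distributed 1D-CNN + GRU segment-quality classifier.

A 1024x3 segment (BCG, IPG, DIPG) is split into two 512-sample sub-windows.
Each sub-window passes a shared three-layer convolution stack (32 filters,
kernel sizes 3/5/13, stride 2, ReLU), a 2x max pool, and a flatten; the
resulting two-step feature sequence feeds a single-layer GRU whose final
hidden state goes through dropout and a 1024-256-1 dense head with a
sigmoid output.  Binary cross-entropy loss, Adam at 1e-4, output threshold
0.5.

The network is implemented directly on NumPy kernels (:mod:`scalebp._nn`)
with analytically derived gradients; the test suite checks every gradient
against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn

__all__ = ["QualityNetConfig", "QualityNet", "build_model", "train", "predict"]


@dataclass(frozen=True)
class QualityNetConfig:
    """Architecture and training hyper-parameters.

    Defaults are the full-scale configuration; ``desk_scale`` returns a
    width-reduced variant for laptop/CI-sized synthetic experiments.
    """

    input_samples: int = 1024
    n_channels: int = 3
    n_sub_windows: int = 2
    conv_filters: int = 32
    kernel_sizes: tuple[int, ...] = (3, 5, 13)
    conv_stride: int = 2
    gru_units: int = 1024
    dense_units: tuple[int, ...] = (1024, 256, 1)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 512
    threshold: float = 0.5
    epochs: int = 14
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if any(k <= 0 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be positive odd integers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.input_samples % self.n_sub_windows:
            raise ValueError("input_samples must divide into the sub-windows")
        if self.dense_units[-1] != 1:
            raise ValueError("final dense layer must have one unit")

    @property
    def sub_window(self) -> int:
        return self.input_samples // self.n_sub_windows

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "QualityNetConfig":
        """Width-reduced configuration for desk-scale synthetic runs.

        Same topology (two shared conv sub-windows -> GRU -> dense head),
        smaller GRU/dense widths, smaller batches, and a learning rate
        matched to the small-batch regime.
        """
        defaults = dict(
            gru_units=256, dense_units=(256, 64, 1), batch_size=64,
            learning_rate=1e-3, seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


class QualityNet:
    """The classifier: parameters, forward/backward, Adam training loop."""

    def __init__(self, config: QualityNetConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self._adam: _nn.AdamState | None = None

    # --- construction -------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        dt = self.dtype

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(dt)

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, shape).astype(dt)

        cin = cfg.n_channels
        length = cfg.sub_window
        for i, k in enumerate(cfg.kernel_sizes):
            self.params[f"conv{i}_w"] = he((k, cin, cfg.conv_filters), k * cin)
            self.params[f"conv{i}_b"] = np.zeros(cfg.conv_filters, dtype=dt)
            cin = cfg.conv_filters
            length = _nn.conv1d_out_len(length, cfg.conv_stride)
        self.feature_dim = (length // 2) * cfg.conv_filters

        h = cfg.gru_units
        for gate in ("z", "r", "n"):
            self.params[f"W{gate}"] = glorot((self.feature_dim, h))
            self.params[f"U{gate}"] = glorot((h, h))
            self.params[f"b{gate}"] = np.zeros(h, dtype=dt)

        fan = h
        for i, units in enumerate(cfg.dense_units):
            self.params[f"dense{i}_w"] = he((fan, units), fan)
            self.params[f"dense{i}_b"] = np.zeros(units, dtype=dt)
            fan = units

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # --- forward ------------------------------------------------------

    def conv_features(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Shared conv stack + pool + flatten -> (B, n_sub_windows, F)."""
        cfg = self.config
        b = x.shape[0]
        h = x.reshape(b * cfg.n_sub_windows, cfg.sub_window, cfg.n_channels)
        h = h.astype(self.dtype, copy=False)
        for i in range(len(cfg.kernel_sizes)):
            pre, cc = _nn.conv1d_forward(
                h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"], cfg.conv_stride
            )
            h = _nn.relu(pre)
            if cache is not None:
                cache.append(("conv", i, cc, h))
        h, idx = _nn.maxpool2_forward(h)
        if cache is not None:
            cache.append(("pool", idx, h.shape))
        return h.reshape(b, cfg.n_sub_windows, self.feature_dim)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list | None]:
        cfg = self.config
        cache: list | None = [] if train else None
        feats = self.conv_features(x, cache)
        h, gru_cache = _nn.gru_forward(feats, self._gru_params())
        if train:
            cache.append(("gru", gru_cache))

        if train and cfg.dropout > 0:
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            mask = mask.astype(self.dtype)
            h = h * mask
            cache.append(("dropout", mask))

        for i in range(len(cfg.dense_units)):
            pre, xc = _nn.dense_forward(
                h, self.params[f"dense{i}_w"], self.params[f"dense{i}_b"]
            )
            last = i == len(cfg.dense_units) - 1
            h = pre if last else _nn.relu(pre)
            if train:
                cache.append(("dense", i, xc, h, last))
        prob = _nn.sigmoid(h[:, 0].astype(np.float64))
        return prob, cache

    def _gru_params(self) -> dict[str, np.ndarray]:
        return {k: self.params[k] for k in ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wn", "Un", "bn")}

    # --- backward -----------------------------------------------------

    def backward(self, prob: np.ndarray, y: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        cfg = self.config
        b = len(y)
        grads: dict[str, np.ndarray] = {}
        # sigmoid + BCE collapse: dL/dlogit = (p - y)/B
        d = ((prob - y) / b).astype(self.dtype)[:, None]

        steps = list(cache)
        while steps:
            step = steps.pop()
            kind = step[0]
            if kind == "dense":
                _, i, xc, _out, last = step
                if not last:
                    d = _nn.relu_grad(d, _out)
                d, dw, db = _nn.dense_backward(d, self.params[f"dense{i}_w"], xc)
                grads[f"dense{i}_w"], grads[f"dense{i}_b"] = dw, db
            elif kind == "dropout":
                d = d * step[1]
            elif kind == "gru":
                dx, gru_grads = _nn.gru_backward(d, self._gru_params(), step[1])
                grads.update(gru_grads)
                d = dx.reshape(-1, self.feature_dim)
            elif kind == "pool":
                _, idx, shape = step
                d = _nn.maxpool2_backward(d.reshape(shape), idx)
            elif kind == "conv":
                _, i, cc, out = step
                d = _nn.relu_grad(d, out)
                d, dw, db = _nn.conv1d_backward(
                    d, self.params[f"conv{i}_w"], cfg.conv_stride, cc
                )
                grads[f"conv{i}_w"], grads[f"conv{i}_b"] = dw, db
        return grads

    # --- training -----------------------------------------------------

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int | None = None,
        batch_size: int | None = None,
        patience: int | None = None,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam training; returns the per-epoch history."""
        cfg = self.config
        y_train = np.asarray(y_train, dtype=np.float64)
        if len(np.unique(y_train)) < 2:
            raise ValueError("training set must contain both quality classes")
        epochs = cfg.epochs if epochs is None else epochs
        batch_size = cfg.batch_size if batch_size is None else batch_size
        rng = np.random.default_rng(cfg.seed + 1)
        if self._adam is None:
            self._adam = _nn.AdamState(self.params, lr=cfg.learning_rate)

        history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }
        best_val, since_best = np.inf, 0
        for epoch in range(epochs):
            order = rng.permutation(len(y_train))
            losses, accs = [], []
            for at in range(0, len(order), batch_size):
                idx = order[at : at + batch_size]
                xb, yb = x_train[idx], y_train[idx]
                prob, cache = self.forward(xb, train=True, rng=rng)
                losses.append(_bce(prob, yb))
                accs.append(float(np.mean((prob >= cfg.threshold) == yb)))
                grads = self.backward(prob, yb, cache)
                _nn.adam_step(self.params, grads, self._adam)
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(float(np.mean(accs)))
            if x_val is not None:
                vp = self.predict_proba(x_val)
                vl = _bce(vp, np.asarray(y_val, dtype=np.float64))
                va = float(np.mean((vp >= cfg.threshold) == y_val))
                history["val_loss"].append(vl)
                history["val_accuracy"].append(va)
                if verbose:
                    print(
                        f"epoch {epoch + 1}/{epochs} loss {history['loss'][-1]:.4f} "
                        f"acc {history['accuracy'][-1]:.4f} val_loss {vl:.4f} val_acc {va:.4f}"
                    )
                if patience is not None:
                    if vl < best_val - 1e-5:
                        best_val, since_best = vl, 0
                    else:
                        since_best += 1
                        if since_best > patience:
                            break
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for at in range(0, len(x), batch_size):
            p, _ = self.forward(x[at : at + batch_size], train=False)
            probs.append(p)
        return np.concatenate(probs)

    def predict(self, x: np.ndarray, threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Labels (1 iff probability >= threshold) and probabilities."""
        thr = self.config.threshold if threshold is None else threshold
        prob = self.predict_proba(x)
        return (prob >= thr).astype(int), prob


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# module-surface conveniences ------------------------------------------------


def build_model(config: QualityNetConfig | None = None) -> QualityNet:
    return QualityNet(config or QualityNetConfig())


def train(model: QualityNet, x_train, y_train, x_val=None, y_val=None, **kwargs):
    history = model.fit(x_train, y_train, x_val, y_val, **kwargs)
    return model, history


def predict(model: QualityNet, segments, threshold: float | None = None):
    return model.predict(segments, threshold)
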