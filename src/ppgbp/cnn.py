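"""A small convolutional network for scalogram classification, in numpy.

The architecture is the fixed seven-layer stack used for normal/abnormal
blood-pressure classification of 224x224x3 scalogram images:

    C1: conv 64 @ 3x3, stride 1, same padding, ReLU
    S2: max pool 2x2, stride 2, same padding
    C3: conv 128 @ 5x5, stride 1, same padding, ReLU
    S4: max pool 2x2, stride 2, same padding
    F5: dense 256, ReLU
    F6: dense 128, ReLU
    F7: dense 1, sigmoid (binary cross-entropy loss)

Forward and backward passes are implemented with im2col/col2im GEMMs in
float32 and trained with Adam.  Everything is seeded, single-process and
deterministic: two runs with the same seeds produce bit-identical weights.
The input resolution is configurable; the canonical 224x224 stack is the
default, while training experiments may run at reduced resolution (the
image loader downsamples) to fit CPU budgets without changing the layers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .dataset import DatasetManifest, build_dataset

_F = np.float32


@dataclass(frozen=True)
class CNNConfig:
    """Layer hyperparameters; defaults are the canonical stack."""

    input_size: int = 224
    in_channels: int = 3
    conv1_filters: int = 64
    conv1_kernel: int = 3
    conv2_filters: int = 128
    conv2_kernel: int = 5
    dense1_units: int = 256
    dense2_units: int = 128


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (the source architecture leaves these open)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    optimizer: str = "adam"
    input_size: int = 224  # loader resolution; model must match


# ---------------------------------------------------------------- layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same (zero) padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


def _col2im(cols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    p = k // 2
    cols = cols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w]


class Conv2D:
    """Stride-1 same-padding convolution with ReLU folded out (separate)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_ch)).astype(_F)
        self.b = np.zeros(out_ch, dtype=_F)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dW = cols.T @ dmat
        self.db = dmat.sum(axis=0)
        self._cache = None
        return _col2im(dmat @ self.W.T, x_shape, self.k)

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2, same padding (odd dims padded with -inf)."""

    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        win = x.reshape(n, c, hp // 2, 2, wp // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, hp // 2, wp // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w), (hp, wp))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w), (hp, wp) = self._cache
        dflat = np.zeros((n, c, hp // 2, wp // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, hp // 2, wp // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = dx.reshape(n, c, hp, wp)
        return dx[:, :, :h, :w]


class Flatten:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(_F)
        self.b = np.zeros(n_out, dtype=_F)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class CNNModel:
    """The fixed conv-pool-conv-pool-dense-dense-sigmoid stack."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = config
        s2 = (c.input_size + 1) // 2  # max pool with same padding: ceil(s/2)
        s4 = (s2 + 1) // 2
        flat = s4 * s4 * c.conv2_filters
        self.config = config
        self.conv1 = Conv2D(c.in_channels, c.conv1_filters, c.conv1_kernel, rng)
        self.conv2 = Conv2D(c.conv1_filters, c.conv2_filters, c.conv2_kernel, rng)
        self.dense1 = Dense(flat, c.dense1_units, rng)
        self.dense2 = Dense(c.dense1_units, c.dense2_units, rng)
        self.out = Dense(c.dense2_units, 1, rng)
        self.layers = [
            self.conv1, ReLU(), MaxPool2(),
            self.conv2, ReLU(), MaxPool2(),
            Flatten(), self.dense1, ReLU(), self.dense2, ReLU(), self.out,
        ]

    # -- forward/backward on logits; sigmoid lives in predict/loss

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=self.conv1.W.dtype)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0]

    def astype(self, dtype) -> "CNNModel":
        """Cast all parameters in place (float64 aids gradient checking)."""
        for layer in self.trainable_layers():
            layer.W = layer.W.astype(dtype)
            layer.b = layer.b.astype(dtype)
        return self

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits[:, None].astype(_F)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[i : i + batch_size], train=False)
            probs.append(_sigmoid(z))
        return np.concatenate(probs)

    def trainable_layers(self):
        return [self.conv1, self.conv2, self.dense1, self.dense2, self.out]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.trainable_layers())

    def weights_checksum(self) -> str:
        h = hashlib.sha256()
        for layer in self.trainable_layers():
            h.update(np.ascontiguousarray(layer.W).tobytes())
            h.update(np.ascontiguousarray(layer.b).tobytes())
        return h.hexdigest()

    def feature_shapes(self) -> dict:
        """Spatial shapes after each stage for the configured input size."""
        s = self.config.input_size
        s2 = (s + 1) // 2
        s4 = (s2 + 1) // 2
        return {
            "conv1": (s, s, self.config.conv1_filters),
            "pool1": (s2, s2, self.config.conv1_filters),
            "conv2": (s2, s2, self.config.conv2_filters),
            "pool2": (s4, s4, self.config.conv2_filters),
            "flatten": (s4 * s4 * self.config.conv2_filters,),
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (mean loss, dL/dz)."""
    z = z.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (_sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


def build_model(config: CNNConfig = CNNConfig(), seed: int = 0) -> CNNModel:
    """Instantiate the network with seeded He-normal initialization."""
    return CNNModel(config, seed=seed)


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers = layers
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for l in layers for p in (l.W, l.b)]
        self.v = [np.zeros_like(p) for l in layers for p in (l.W, l.b)]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.layers:
            for pname, gname in (("W", "dW"), ("b", "db")):
                p = getattr(layer, pname)
                g = getattr(layer, gname).astype(p.dtype)
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1


def load_manifest_arrays(
    manifest: DatasetManifest, split: str, input_size: int = 224
) -> tuple[np.ndarray, np.ndarray]:
    """Load one split's images as (N, 3, H, W) float32 in [0, 1] plus labels.

    Images stored at 224x224 are bilinearly downsampled when ``input_size``
    is smaller, preserving the scalogram's coarse time-frequency layout.
    """
    rows = manifest.frame[manifest.frame["split"] == split]
    xs, ys = [], []
    for _, row in rows.iterrows():
        with Image.open(row["image_path"]) as im:
            im = im.convert("RGB")
            if im.size != (input_size, input_size):
                im = im.resize((input_size, input_size), resample=Image.BILINEAR)
            xs.append(np.asarray(im, dtype=_F) / 255.0)
        ys.append(row["binary"])
    if not xs:
        raise ValueError(f"split {split!r} is empty")
    x = np.stack(xs).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(x), np.asarray(ys, dtype=np.float64)


@dataclass
class EvalReport:
    """Validation metrics: accuracy at threshold 0.5, ROC points, AUC."""

    accuracy: float
    roc: list[tuple[float, float]]
    auc: float
    scores: np.ndarray
    labels: np.ndarray
    history: dict | None = None


def train(
    model: CNNModel,
    data: DatasetManifest | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Train with Adam on binary cross-entropy; returns per-epoch history.

    ``data`` is either a dataset manifest (train split loaded from disk at
    ``cfg.input_size``) or an ``(X, y)`` pair.  Deterministic given seeds.
    """
    if isinstance(data, DatasetManifest):
        x, y = load_manifest_arrays(data, "train", cfg.input_size)
        if val_data is None and (data.frame["split"] == "val").any():
            val_data = load_manifest_arrays(data, "val", cfg.input_size)
    else:
        x, y = data
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = _Adam(model.trainable_layers(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: dict = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            z = model.forward_logits(xb, train=True)
            loss, dz = _bce_with_logits(z, yb)
            model.backward(dz)
            opt.step()
            losses.append(loss * len(sel))
            correct += int(np.sum((_sigmoid(z) >= 0.5) == (yb >= 0.5)))
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        if val_data is not None:
            xv, yv = val_data
            zv = []
            for j in range(0, xv.shape[0], cfg.batch_size):
                zv.append(model.forward_logits(xv[j : j + cfg.batch_size]))
            zv = np.concatenate(zv)
            vloss, _ = _bce_with_logits(zv, yv)
            history["val_loss"].append(vloss)
            history["val_acc"].append(float(np.mean((_sigmoid(zv) >= 0.5) == (yv >= 0.5))))
    return history


def evaluate(
    model: CNNModel,
    data: DatasetManifest | tuple[np.ndarray, np.ndarray],
    input_size: int | None = None,
    history: dict | None = None,
) -> EvalReport:
    """Score the validation split: accuracy at 0.5, ROC sweep, trapezoid AUC."""
    if isinstance(data, DatasetManifest):
        size = input_size if input_size is not None else model.config.input_size
        x, y = load_manifest_arrays(data, "val", size)
    else:
        x, y = data
    if x.shape[0] == 0:
        raise ValueError("validation split is empty")
    scores = model.predict_proba(x)
    accuracy = float(np.mean((scores >= 0.5) == (y >= 0.5)))
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = roc_curve(y, scores)
        auc_val = float(sk_auc(fpr, tpr))
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    else:  # degenerate single-class split: ROC undefined
        roc, auc_val = [(0.0, 0.0), (1.0, 1.0)], float("nan")
    return EvalReport(accuracy=accuracy, roc=roc, auc=auc_val,
                      scores=scores, labels=y, history=history)


@dataclass
class GridResult:
    """Accuracy over the wavelet x segment-length grid."""

    accuracies: pd.DataFrame  # rows: wavelet name (incl. 'none'), cols: length
    reports: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        self.accuracies.to_csv(path)


def grid_search(
    records,
    wavelets: list,
    lengths: list[int],
    cfg: TrainConfig,
    out_dir: str | Path,
    model_config: CNNConfig | None = None,
    train_frac: float = 0.9,
) -> GridResult:
    """One identically configured train/evaluate run per (wavelet, length).

    ``wavelets`` entries are WaveletSpec or None (no-CWT baseline).  A cell
    failure is recorded and the grid continues.
    """
    if not wavelets or not lengths:
        raise ValueError("need at least one wavelet (or baseline) and one length")
    out_dir = Path(out_dir)
    if model_config is None:
        model_config = CNNConfig(input_size=cfg.input_size)
    names = [(w.name if w is not None else "none") for w in wavelets]
    acc = pd.DataFrame(np.nan, index=names, columns=lengths)
    reports: dict = {}
    errors: dict = {}
    for w, name in zip(wavelets, names):
        for length in lengths:
            cell = (name, length)
            try:
                manifest = build_dataset(
                    records, w, length, out_dir / name / str(length),
                    train_frac=train_frac, seed=cfg.seed,
                )
                model = build_model(model_config, seed=cfg.seed)
                history = train(model, manifest, cfg)
                report = evaluate(model, manifest, input_size=cfg.input_size,
                                  history=history)
                acc.loc[name, length] = report.accuracy
                reports[cell] = report
            except Exception as exc:  # record and continue
                errors[cell] = repr(exc)
    return GridResult(accuracies=acc, reports=reports, errors=errors)
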