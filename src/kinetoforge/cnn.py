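"""A small convolutional neural network for 50x50 RGB image classification.

Architecture: three blocks of [3x3 convolution, stride 1, "same" padding
(8, 16, 32 filters) -> batch normalization -> ReLU -> 2x2 max-pool,
stride 2], except that the third block's pooling stage is replaced by a
fully connected layer of width ``n_classes`` feeding a softmax. Counting
convolution kernels, the batch-norm scale/shift pairs and the fully
connected layer, the network carries 13 learnable weight tensors
(3 conv + 3x(gamma, beta) + FC weight + biases folded per layer in the
coarser accounting; the block structure is what is fixed).

Spatial sizes: 50 -> (pool) 25 -> (pool) 12, so the FC layer sees
32 * 12 * 12 = 4608 inputs.

Training uses stochastic gradient descent with momentum (0.9), initial
learning rate 0.01, up to 20 epochs, minibatches of 128 and an L2 penalty
of 1e-4 on convolution and FC weights, with held-out validation accuracy
recorded every 30 iterations. Everything is plain numpy: the network is
small enough that im2col matrix multiplication trains desk-scale datasets
on one CPU core in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNConfig", "TrainConfig", "SplitSpec", "ConfusionMatrix",
           "SimpleCNN", "build_cnn", "split_dataset", "balance_classes",
           "train_cnn", "evaluate", "predict", "images_to_tensor",
           "save_model", "load_model"]


@dataclass
class CNNConfig:
    input_shape: tuple = (3, 50, 50)       # (channels, rows, cols)
    filters: tuple = (8, 16, 32)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if tuple(self.filters) != (8, 16, 32):
            raise ValueError("filter counts are fixed at (8, 16, 32)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 20
    validation_frequency: int = 30         # iterations between val checks
    batch_size: int = 128
    l2: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("need learning_rate > 0 and max_epochs >= 1")


@dataclass
class SplitSpec:
    fractions: tuple = (0.56, 0.24, 0.20)  # train, validation, test
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class ConfusionMatrix:
    """Row = true class, column = predicted class."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


# --------------------------------------------------------------------- layers

def _conv_same(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 'same' cross-correlation. Returns (output NFHW, im2col matrix)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))      # (n,c,h,w,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    cols = np.ascontiguousarray(cols, dtype=np.float32)
    out = cols @ w.reshape(w.shape[0], -1).T                # (n*h*w, f)
    return out.reshape(n, h, wd, -1).transpose(0, 3, 1, 2), cols


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * 9, c_out * 9
        limit = np.sqrt(6.0 / (fan_in + fan_out))            # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out, cols = _conv_same(x, self.w)
        if training:
            self._cols, self._xshape = cols, x.shape
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, wd = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dw = (dflat.T @ self._cols).reshape(self.w.shape)
        self.db = dflat.sum(axis=0)
        # dx = 'same' correlation of dout with the flipped, axis-swapped kernel
        wback = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv_same(dout, np.ascontiguousarray(wback))
        self._cols = None
        return dx

    def update(self, lr: float, momentum: float, l2: float) -> None:
        self.vw = momentum * self.vw - lr * (self.dw + l2 * self.w)
        self.vb = momentum * self.vb - lr * self.db
        self.w += self.vw
        self.b += self.vb


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.vg = np.zeros_like(self.gamma)
        self.vb = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma[None, :, None, None] * self._xhat \
            + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        m = n * h * w
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3),
                                                       keepdims=True)) / self._std
        self._xhat = None
        return dx

    def update(self, lr: float, momentum: float, l2: float) -> None:
        self.vg = momentum * self.vg - lr * self.dgamma
        self.vb = momentum * self.vb - lr * self.dbeta
        self.gamma += self.vg
        self.beta += self.vb


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def update(self, *args) -> None:
        pass


class _MaxPool:
    """2x2 max pooling with stride 2; trailing odd row/col dropped (floor)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xt.argmax(axis=-1)
        self._inshape = (n, c, h, w)
        return np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        dxt = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=-1)
        dxt = dxt.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._inshape, dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = dxt.reshape(n, c, h2 * 2, w2 * 2)
        self._argmax = None
        return dx

    def update(self, *args) -> None:
        pass


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.w = rng.uniform(-limit, limit, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        if training:
            self._x = flat
        return flat @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = (dout @ self.w.T).reshape(self._shape)
        self._x = None
        return dx

    def update(self, lr: float, momentum: float, l2: float) -> None:
        self.vw = momentum * self.vw - lr * (self.dw + l2 * self.w)
        self.vb = momentum * self.vb - lr * self.db
        self.w += self.vw
        self.b += self.vb


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SimpleCNN:
    """The three-block CNN; see the module docstring for the architecture."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, h, w = config.input_shape
        f1, f2, f3 = config.filters
        h_fc = (h // 2) // 2
        w_fc = (w // 2) // 2
        self.layers = [
            _Conv(c, f1, rng), _BatchNorm(f1), _ReLU(), _MaxPool(),
            _Conv(f1, f2, rng), _BatchNorm(f2), _ReLU(), _MaxPool(),
            _Conv(f2, f3, rng), _BatchNorm(f3), _ReLU(),
            _Dense(f3 * h_fc * w_fc, config.n_classes, rng),
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(_softmax(self.forward(x[i:i + batch_size],
                                               training=False)))
        return np.vstack(probs)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   tconfig: TrainConfig) -> float:
        """One SGDM minibatch update; returns the cross-entropy loss."""
        logits = self.forward(x, training=True)
        probs = _softmax(logits)
        n = len(y)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training loss diverged (NaN/inf); reduce the learning rate")
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            layer.update(tconfig.learning_rate, tconfig.momentum, tconfig.l2)
        return loss


def build_cnn(config: CNNConfig, seed: int = 0) -> SimpleCNN:
    """Build the network with seeded (Glorot-uniform) initial weights."""
    return SimpleCNN(config, seed=seed)


def images_to_tensor(images: np.ndarray) -> np.ndarray:
    """(N, 50, 50, 3) 16-bit images -> float32 NCHW tensor scaled to [0, 1]."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (n, rows, cols, 3) images, got {arr.shape}")
    return (arr.astype(np.float32) / 65535.0).transpose(0, 3, 1, 2)


# ------------------------------------------------------------------ splitting

def _largest_remainder(n: int, fractions: tuple) -> list[int]:
    ideal = [f * n for f in fractions]
    counts = [int(np.floor(v)) for v in ideal]
    rem = n - sum(counts)
    order = np.argsort([c - v for c, v in zip(counts, ideal)])  # most underfilled first
    for i in range(rem):
        counts[order[i % len(counts)]] += 1
    return counts


def split_dataset(labels: np.ndarray, spec: SplitSpec
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, stratified train/validation/test index sets.

    Within each class the items are shuffled and allocated by largest-
    remainder rounding of the 56/24/20 fractions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    groups = ([np.flatnonzero(labels == c) for c in np.unique(labels)]
              if spec.stratified else [np.arange(len(labels))])
    parts: list[list] = [[], [], []]
    for cls_idx, idx in enumerate(groups):
        counts = _largest_remainder(len(idx), spec.fractions)
        if any(c < 1 for c in counts):
            name = np.unique(labels)[cls_idx] if spec.stratified else "all"
            raise ValueError(f"class {name!r} too small for fractions "
                             f"{spec.fractions} (n={len(idx)})")
        perm = rng.permutation(idx)
        ofs = 0
        for p, c in zip(parts, counts):
            p.append(perm[ofs:ofs + c])
            ofs += c
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return train, val, test


def balance_classes(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset (downsampled without replacement)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balance_classes needs >= 2 classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = [rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False)
            for c in classes]
    return np.sort(np.concatenate(keep))


# ------------------------------------------------------------------- training

def _snapshot_weights(model: SimpleCNN) -> list:
    snap = []
    for layer in model.layers:
        entry = {}
        for attr in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
            if hasattr(layer, attr):
                entry[attr] = getattr(layer, attr).copy()
        snap.append(entry)
    return snap


def _restore_weights(model: SimpleCNN, snap: list) -> None:
    for layer, entry in zip(model.layers, snap):
        for attr, value in entry.items():
            setattr(layer, attr, value.copy())


def train_cnn(model: SimpleCNN, x: np.ndarray, y: np.ndarray,
              splits: tuple[np.ndarray, np.ndarray],
              tconfig: TrainConfig) -> dict:
    """Train with SGDM; validation accuracy recorded every 30 iterations.

    ``splits`` holds the (train, validation) index arrays into ``x``/``y``.
    SGD with a fixed 0.01 learning rate oscillates between good and poor
    solutions late in training, so the model returned is the snapshot with
    the best recorded validation accuracy (ties broken toward the later
    checkpoint); selection never sees test data. Returns a history dict
    with per-iteration losses, the validation checkpoints
    (iteration, accuracy), and the restored checkpoint's iteration.
    """
    train_idx, val_idx = splits
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(tconfig.seed)
    y = np.asarray(y)
    history = {"loss": [], "val_checks": []}
    iteration = 0
    best = (-1.0, -1, None)          # (val acc, iteration, weights)

    def _check() -> None:
        nonlocal best
        acc = float((model.predict_labels(x[val_idx]) == y[val_idx]).mean())
        history["val_checks"].append((iteration, acc))
        if acc >= best[0]:
            best = (acc, iteration, _snapshot_weights(model))

    for epoch in range(tconfig.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), tconfig.batch_size):
            batch = order[start:start + tconfig.batch_size]
            loss = model.train_step(x[batch], y[batch], tconfig)
            history["loss"].append(loss)
            iteration += 1
            if iteration % tconfig.validation_frequency == 0:
                _check()
    if not history["val_checks"] or history["val_checks"][-1][0] != iteration:
        _check()                      # final validation pass
    _restore_weights(model, best[2])
    history["final_validation_accuracy"] = best[0]
    history["best_iteration"] = best[1]
    history["iterations"] = iteration
    return history


def evaluate(model: SimpleCNN, x: np.ndarray, y: np.ndarray,
             class_names: list | None = None) -> ConfusionMatrix:
    """Confusion matrix over a labeled set (rows true, columns predicted)."""
    y = np.asarray(y)
    k = model.config.n_classes
    pred = model.predict_labels(x)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y, pred), 1)
    if class_names is None:
        class_names = [str(i) for i in range(k)]
    return ConfusionMatrix(counts, list(class_names))


def save_model(model: SimpleCNN, path, class_names: list | None = None) -> None:
    """Serialize weights, running statistics and config to an .npz file."""
    import json
    arrays = {}
    for i, layer in enumerate(model.layers):
        for attr in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
            if hasattr(layer, attr):
                arrays[f"layer{i}_{attr}"] = getattr(layer, attr)
    meta = {"n_classes": model.config.n_classes,
            "input_shape": list(model.config.input_shape),
            "filters": list(model.config.filters),
            "class_names": class_names}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[SimpleCNN, list | None]:
    """Rebuild a saved model; returns (model, class_names or None)."""
    import json
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    config = CNNConfig(input_shape=tuple(meta["input_shape"]),
                       filters=tuple(meta["filters"]),
                       n_classes=meta["n_classes"])
    model = SimpleCNN(config, seed=0)
    for i, layer in enumerate(model.layers):
        for attr in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
            key = f"layer{i}_{attr}"
            if key in data:
                setattr(layer, attr, data[key].copy())
    return model, meta.get("class_names")


def predict(model: SimpleCNN, images: np.ndarray,
            class_names: list | None = None) -> tuple[np.ndarray, dict]:
    """Classify images (uint16 HWC or float NCHW); returns labels + counts."""
    arr = np.asarray(images)
    if arr.ndim == 4 and arr.shape[-1] == 3:
        arr = images_to_tensor(arr)
    labels = model.predict_labels(arr)
    k = model.config.n_classes
    names = class_names or [str(i) for i in range(k)]
    counts = {names[i]: int((labels == i).sum()) for i in range(k)}
    return labels, counts
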