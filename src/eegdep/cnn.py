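"""Convolutional classifier producing an AI score in [0, 1].

Architecture: three convolutional layers (11x11/128, 5x5/256, 3x3/256
by default), max-pooling after the first two, and three fully connected
layers ending in a single sigmoid unit. Dropout and L2 weight decay act
on the fully connected layers. Training is plain stochastic gradient
descent (with momentum) on binary cross-entropy, batch size 32, 20
epochs; per-epoch training and validation accuracies are recorded and
the optimal epoch is selected from them.

The network is implemented directly on NumPy (im2col convolutions,
manual backpropagation); everything is deterministic given the
configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ConvSpec:
    kernel: int
    filters: int
    stride: int = 1


@dataclass
class CNNConfig:
    """Architecture and optimisation hyperparameters."""

    input_size: int = 400
    conv1: ConvSpec = field(default_factory=lambda: ConvSpec(11, 128, 4))
    conv2: ConvSpec = field(default_factory=lambda: ConvSpec(5, 256, 1))
    conv3: ConvSpec = field(default_factory=lambda: ConvSpec(3, 256, 1))
    fc_sizes: tuple[int, int] = (256, 64)  # two hidden FC widths; output is 1
    dropout_rate: float = 0.5
    l2_lambda: float = 1e-4
    lr: float = 1e-4
    momentum: float = 0.9
    optimizer: str = "sgd"  # or "adam"
    batch_size: int = 32
    epochs: int = 20
    selection: str = "min_train_val"  # or "val"
    augment_shift: bool = False  # random circular time-shift per presentation
    batch_norm: bool = False  # normalise conv activations per batch
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv1", "conv2", "conv3"):
            v = getattr(self, name)
            if isinstance(v, (tuple, list)):
                setattr(self, name, ConvSpec(*v))
            elif isinstance(v, dict):
                setattr(self, name, ConvSpec(**v))
        self.fc_sizes = tuple(self.fc_sizes)
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.selection not in ("min_train_val", "val"):
            raise ValueError(f"unknown selection rule {self.selection!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def reduced(cls, seed: int = 0) -> "CNNConfig":
        """Small configuration for 100x100 inputs (tests, demos)."""
        return cls(
            input_size=100,
            conv1=ConvSpec(11, 8, 2),
            conv2=ConvSpec(5, 16, 1),
            conv3=ConvSpec(3, 16, 1),
            fc_sizes=(32, 16),
            dropout_rate=0.25,
            lr=0.01,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# layers

def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N, oh*ow, C*k*k) patches."""
    n, c, h, w = x.shape
    if h < k or w < k:
        raise ValueError(f"input {h}x{w} smaller than kernel {k}")
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


class _Conv:
    def __init__(self, c_in: int, spec: ConvSpec, rng: np.random.Generator):
        k, f = spec.kernel, spec.filters
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, f)).astype(
            np.float32
        )
        self.b = np.zeros(f, dtype=np.float32)
        self.spec = spec
        self.c_in = c_in
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, oh, ow = _im2col(x, self.spec.kernel, self.spec.stride)
        out = cols @ self.w + self.b
        if train:
            self._cache = (cols, x.shape, oh, ow)
        n = x.shape[0]
        return out.reshape(n, oh, ow, self.spec.filters).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        k, s = self.spec.kernel, self.spec.stride
        d = dout.transpose(0, 2, 3, 1).reshape(n, oh * ow, self.spec.filters)
        self.grads["w"] = np.tensordot(cols, d, axes=([0, 1], [0, 1]))
        self.grads["b"] = d.sum(axis=(0, 1))
        dcols = d @ self.w.T  # (n, oh*ow, c*k*k)
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dx = np.zeros(x_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        arg = xv.argmax(axis=-1)
        out = np.take_along_axis(xv, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, arg)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, arg = self._cache
        n, c, h, w = x_shape
        h2, w2 = h // 2, w // 2
        dxv = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dxv, arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dxv.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class _BatchNorm2d:
    """Per-channel batch normalisation with learned scale/shift."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.w = np.ones(n_ch, dtype=np.float32)  # gamma
        self.b = np.zeros(n_ch, dtype=np.float32)  # beta
        self.run_mean = np.zeros(n_ch, dtype=np.float32)
        self.run_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.w[None, :, None, None] * xhat + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.grads["w"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.w[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        if not train or self.rate == 0.0 or rng is None:
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask.astype(np.float32)


# ---------------------------------------------------------------------------
# model

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CNNModel:
    """The classifier: build, train, score.

    ``history`` holds one ``(train_acc, val_acc, train_loss)`` triple per
    epoch after :meth:`fit`; scoring uses the weights of the selected
    optimal epoch.
    """

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xC0FFEE])
        s = config.input_size
        if s < config.conv1.kernel:
            raise ValueError(f"input size {s} smaller than conv1 kernel")
        self.conv_layers = []
        c_in = 1
        size = s
        for spec, pool in (
            (config.conv1, True),
            (config.conv2, True),
            (config.conv3, False),
        ):
            conv = _Conv(c_in, spec, rng)
            size = (size - spec.kernel) // spec.stride + 1
            if size < 1:
                raise ValueError("feature map collapsed; incompatible input size")
            stack: list = [conv]
            if config.batch_norm:
                stack.append(_BatchNorm2d(spec.filters))
            stack.append(_ReLU())
            if pool:
                stack.append(_MaxPool2())
                size //= 2
            self.conv_layers.append(stack)
            c_in = spec.filters
        self._final_c = c_in
        self._final_s = size
        self._flat = size * size * c_in
        f1, f2 = config.fc_sizes
        self.fc1 = _Dense(self._flat, f1, rng)
        self.fc2 = _Dense(f1, f2, rng)
        self.fc3 = _Dense(f2, 1, rng)
        self.do1 = _Dropout(config.dropout_rate)
        self.do2 = _Dropout(config.dropout_rate)
        self._relu1, self._relu2 = _ReLU(), _ReLU()
        self.history: list[tuple[float, float, float]] = []
        self.best_epoch: int | None = None

    # -- plumbing -----------------------------------------------------------

    @property
    def fc_layers(self) -> list[_Dense]:
        return [self.fc1, self.fc2, self.fc3]

    def _param_layers(self):
        for stack in self.conv_layers:
            for layer in stack:
                if hasattr(layer, "grads"):
                    yield layer
        yield from self.fc_layers

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_params for layer in self._param_layers())

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim == 2:
            x = x[None]
        s = self.config.input_size
        if x.ndim != 3 or x.shape[1] != s or x.shape[2] != s:
            raise ValueError(
                f"expected ({s}, {s}) grayscale images, got shape {x.shape}"
            )
        # mid-gray (128 = 0 uV) maps to 0; /32 brings typical EEG feature
        # maps to roughly unit variance so He-initialised layers train well
        return ((x.astype(np.float32) - 128.0) / 32.0)[:, None, :, :]

    def _forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        for stack in self.conv_layers:
            for layer in stack:
                x = layer.forward(x, train)
        x = x.reshape(x.shape[0], -1)
        x = self._relu1.forward(self.fc1.forward(x, train), train)
        x = self.do1.forward(x, train, rng)
        x = self._relu2.forward(self.fc2.forward(x, train), train)
        x = self.do2.forward(x, train, rng)
        return self.fc3.forward(x, train)[:, 0]

    def _backward(self, dlogit: np.ndarray) -> None:
        d = self.fc3.backward(dlogit[:, None])
        d = self.do2.backward(d)
        d = self.fc2.backward(self._relu2.backward(d))
        d = self.do1.backward(d)
        d = self.fc1.backward(self._relu1.backward(d))
        d = d.reshape(d.shape[0], self._final_c, self._final_s, self._final_s)
        for stack in reversed(self.conv_layers):
            for layer in reversed(stack):
                d = layer.backward(d)

    # -- scoring ------------------------------------------------------------

    def predict_scores(self, images: np.ndarray, batch: int = 64) -> np.ndarray:
        """AI scores in [0, 1] for a stack of images."""
        x = self._prepare(images)
        out = [
            _sigmoid(self._forward(x[i : i + batch], train=False))
            for i in range(0, x.shape[0], batch)
        ]
        return np.concatenate(out) if out else np.empty(0)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        train_images: np.ndarray,
        train_labels: np.ndarray,
        val_images: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
    ) -> "CNNModel":
        """SGD-with-momentum training on binary cross-entropy."""
        cfg = self.config
        y = np.asarray(train_labels, dtype=np.float32)
        if np.unique(y).size < 2:
            raise ValueError("training set must contain both classes")
        x = self._prepare(train_images)
        has_val = val_images is not None and len(val_images) > 0
        if has_val:
            xv = self._prepare(val_images)
            yv = np.asarray(val_labels, dtype=np.float32)
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x5EED])
        state = {
            id(layer): {
                k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
                for k, v in (("w", layer.w), ("b", layer.b))
            }
            for layer in self._param_layers()
        }
        adam_t = 0
        fc_ids = {id(layer) for layer in self.fc_layers}
        self.history = []
        best_stat = -np.inf
        best_weights = None
        n = x.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            correct = 0
            loss_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                if cfg.augment_shift:
                    # label-preserving views: EEG feature maps are
                    # translation-invariant along time, sign-symmetric in
                    # amplitude, and statistically time-reversible
                    shifts = rng.integers(0, xb.shape[-1], size=len(idx))
                    xb = np.stack(
                        [np.roll(im, s, axis=-1) for im, s in zip(xb, shifts)]
                    )
                    neg = rng.random(len(idx)) < 0.5
                    xb[neg] = -xb[neg]
                    rev = rng.random(len(idx)) < 0.5
                    xb[rev] = xb[rev, :, :, ::-1]
                z = self._forward(xb, train=True, rng=rng)
                p = _sigmoid(z)
                loss = np.mean(
                    np.maximum(z, 0.0) - z * yb + np.log1p(np.exp(-np.abs(z)))
                )
                loss_sum += float(loss) * len(idx)
                correct += int(((p >= 0.5) == (yb >= 0.5)).sum())
                self._backward((p - yb).astype(np.float32) / len(idx))
                adam_t += 1
                for layer in self._param_layers():
                    grads = {"w": layer.grads["w"], "b": layer.grads["b"]}
                    if cfg.l2_lambda and id(layer) in fc_ids:
                        grads["w"] = grads["w"] + cfg.l2_lambda * layer.w
                    st = state[id(layer)]
                    for k, param in (("w", layer.w), ("b", layer.b)):
                        g = grads[k]
                        if cfg.optimizer == "adam":
                            s = st[k]
                            s["m"] = 0.9 * s["m"] + 0.1 * g
                            s["v"] = 0.999 * s["v"] + 0.001 * np.square(g)
                            mhat = s["m"] / (1 - 0.9**adam_t)
                            vhat = s["v"] / (1 - 0.999**adam_t)
                            param -= cfg.lr * mhat / (np.sqrt(vhat) + 1e-8)
                        else:
                            s = st[k]
                            s["m"] = cfg.momentum * s["m"] - cfg.lr * g
                            param += s["m"]
            train_acc = correct / n
            if has_val:
                pv = _sigmoid(self._forward(xv, train=False))
                val_acc = float(np.mean((pv >= 0.5) == (yv >= 0.5)))
            else:
                val_acc = train_acc
            self.history.append((train_acc, val_acc, loss_sum / n))
            stat = self._selection_stat(train_acc, val_acc)
            if stat > best_stat:
                best_stat = stat
                best_weights = self._snapshot()
                self.best_epoch = epoch + 1
        if best_weights is not None:
            self._restore(best_weights)
        return self

    def _selection_stat(self, train_acc: float, val_acc: float) -> float:
        if self.config.selection == "val":
            return val_acc
        return min(train_acc, val_acc)

    def _snapshot(self) -> list[dict]:
        snap = []
        for layer in self._param_layers():
            s = {"w": layer.w.copy(), "b": layer.b.copy()}
            if isinstance(layer, _BatchNorm2d):
                s["run_mean"] = layer.run_mean.copy()
                s["run_var"] = layer.run_var.copy()
            snap.append(s)
        return snap

    def _restore(self, weights) -> None:
        for layer, s in zip(self._param_layers(), weights):
            layer.w[...] = s["w"]
            layer.b[...] = s["b"]
            if isinstance(layer, _BatchNorm2d):
                layer.run_mean[...] = s["run_mean"]
                layer.run_var[...] = s["run_var"]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self._param_layers()):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
            if isinstance(layer, _BatchNorm2d):
                arrays[f"rm{i}"] = layer.run_mean
                arrays[f"rv{i}"] = layer.run_var
        cfg = self.config.to_dict()
        np.savez(
            path,
            __config__=json.dumps(cfg),
            __history__=np.array(self.history, dtype=np.float64).reshape(-1, 3),
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CNNModel":
        with np.load(path, allow_pickle=False) as npz:
            cfg = json.loads(str(npz["__config__"]))
            model = cls(CNNConfig(**cfg))
            for i, layer in enumerate(model._param_layers()):
                layer.w[...] = npz[f"w{i}"]
                layer.b[...] = npz[f"b{i}"]
                if isinstance(layer, _BatchNorm2d):
                    layer.run_mean[...] = npz[f"rm{i}"]
                    layer.run_var[...] = npz[f"rv{i}"]
            model.history = [tuple(row) for row in npz["__history__"]]
        return model


def reduced_training_config(seed: int = 0) -> CNNConfig:
    """Training configuration for the reduced 100x100 demonstration runs.

    Compared with the default (which mirrors the full-size reference
    setup), this trades architecture width for CPU feasibility and
    leans on adaptive optimisation plus label-preserving augmentation,
    which small-sample texture learning needs.
    """
    return CNNConfig(
        input_size=100,
        conv1=ConvSpec(11, 8, 2),
        conv2=ConvSpec(5, 16, 1),
        conv3=ConvSpec(3, 16, 1),
        fc_sizes=(32, 16),
        dropout_rate=0.25,
        l2_lambda=1e-3,
        lr=1e-3,
        batch_size=32,
        epochs=100,
        optimizer="adam",
        augment_shift=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# module-level operations

def build_model(config: CNNConfig) -> CNNModel:
    """Construct an untrained network for 400x400 (or configured) input."""
    return CNNModel(config)


def train(
    model: CNNModel,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> CNNModel:
    return model.fit(train_images, train_labels, val_images, val_labels)


def predict_ai_score(model: CNNModel, image: np.ndarray) -> float:
    """Score one image; classification label is score >= 0.5."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single 2-D image, got shape {image.shape}")
    return float(model.predict_scores(image[None])[0])


def select_best_epoch(history: list[tuple], selection: str = "min_train_val") -> int:
    """1-based index of the optimal epoch; ties go to the earliest."""
    if not history:
        raise ValueError("history is empty")
    if selection == "val":
        stats = [h[1] for h in history]
    elif selection == "min_train_val":
        stats = [min(h[0], h[1]) for h in history]
    else:
        raise ValueError(f"unknown selection rule {selection!r}")
    return int(np.argmax(stats)) + 1
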