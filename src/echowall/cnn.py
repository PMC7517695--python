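"""A small convolutional network implemented directly on numpy.

The localizer is a 7-layer net — conv C1, pool P1, conv C2, pool P2, two
fully connected layers FC1/FC2 (each followed by dropout during training)
and a 2-way softmax head. Convolutions and poolings are *valid* (no
padding); C1/C2 use 3x3 kernels at stride 1, P1 is 3x3 max-pooling at
stride 2 and P2 3x3 max-pooling at stride 1, so a 208x208 single-channel
input flows 208 -> 206 -> 102 -> 100 -> 98 before flattening.

Everything (forward, backward, SGD) is plain numpy in float32: the batches
and layer widths involved are small enough that im2col + BLAS matmuls are
entirely adequate on one CPU core.

Tensors are channels-last: ``(batch, height, width, channels)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import ParameterError


def conv_output_size(input_side: int, kernel: int, stride: int = 1) -> int:
    """Spatial output side of a valid convolution or pooling.

    ``floor((input_side - kernel) / stride) + 1``; raises if the kernel
    does not fit.
    """
    if kernel < 1 or stride < 1:
        raise ParameterError(f"kernel ({kernel}) and stride ({stride}) must be >= 1")
    if kernel > input_side:
        raise ParameterError(
            f"kernel ({kernel}) exceeds input side ({input_side})")
    return (input_side - kernel) // stride + 1


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B,OH,OW,k*k*C) patch matrix for a stride-1 valid conv."""
    b, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((b, oh, ow, k * k, c), dtype=x.dtype)
    for ky in range(k):
        for kx in range(k):
            cols[:, :, :, ky * k + kx, :] = x[:, ky:ky + oh, kx:kx + ow, :]
    return cols.reshape(b, oh, ow, k * k * c)


def _col2im(dcols: np.ndarray, k: int, h: int, w: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    b, oh, ow, _ = dcols.shape
    dcols = dcols.reshape(b, oh, ow, k * k, c)
    dx = np.zeros((b, h, w, c), dtype=dcols.dtype)
    for ky in range(k):
        for kx in range(k):
            dx[:, ky:ky + oh, kx:kx + ow, :] += dcols[:, :, :, ky * k + kx, :]
    return dx


class _Conv:
    """Valid 3x3-style convolution, stride 1, with ReLU."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        cols = _im2col(x, self.k)
        z = cols @ self.W + self.b
        y = np.maximum(z, 0.0)
        if cache is not None:
            cache["cols"] = cols
            cache["relu_mask"] = z > 0
            cache["x_shape"] = x.shape
        return y

    def backward(self, dy: np.ndarray, cache: dict, *, need_dx: bool) -> np.ndarray | None:
        dz = dy * cache["relu_mask"]
        cols = cache["cols"]
        b, oh, ow, kk = cols.shape
        self.dW = cols.reshape(-1, kk).T @ dz.reshape(-1, self.c_out)
        self.db = dz.sum(axis=(0, 1, 2))
        if not need_dx:
            return None
        dcols = dz @ self.W.T
        _, h, w, c = cache["x_shape"]
        return _col2im(dcols, self.k, h, w, c)


class _MaxPool:
    """Max pooling via k*k shifted strided views (no window materialization).

    Backward routes each output gradient to the first (row-major) input
    position attaining the window maximum.
    """

    def __init__(self, k: int, stride: int):
        self.k, self.stride = k, stride

    def _shifts(self, x: np.ndarray, oh: int, ow: int):
        k, s = self.k, self.stride
        for pos in range(k * k):
            ky, kx = divmod(pos, k)
            yield x[:, ky:ky + s * (oh - 1) + 1:s, kx:kx + s * (ow - 1) + 1:s, :]

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        k, s = self.k, self.stride
        b, h, w, c = x.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        y = None
        for view in self._shifts(x, oh, ow):
            y = view.copy() if y is None else np.maximum(y, view, out=y)
        if cache is not None:
            cache["x"] = x
            cache["y"] = y
        return y

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        k, s = self.k, self.stride
        b, oh, ow, c = dy.shape
        x, y = cache["x"], cache["y"]
        dx = np.zeros_like(x)
        taken = np.zeros(dy.shape, dtype=bool)
        sel = np.empty(dy.shape, dtype=bool)
        contrib = np.empty(dy.shape, dtype=dy.dtype)
        for pos in range(k * k):
            ky, kx = divmod(pos, k)
            view = x[:, ky:ky + s * (oh - 1) + 1:s, kx:kx + s * (ow - 1) + 1:s, :]
            np.equal(view, y, out=sel)
            sel &= ~taken
            taken |= sel
            np.multiply(dy, sel, out=contrib)
            dx[:, ky:ky + s * (oh - 1) + 1:s, kx:kx + s * (ow - 1) + 1:s, :] += contrib
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        z = x @ self.W + self.b
        y = np.maximum(z, 0.0) if self.relu else z
        if cache is not None:
            cache["x"] = x
            cache["relu_mask"] = (z > 0) if self.relu else None
        return y

    def backward(self, dy: np.ndarray, cache: dict) -> np.ndarray:
        dz = dy * cache["relu_mask"] if self.relu else dy
        self.dW = cache["x"].T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T


@dataclass
class LocatorConfig:
    """Architecture of the window classifier.

    The layer plan is C1(3x3, s1, 16ch) -> P1(3x3, s2) -> C2(3x3, s1, 16ch)
    -> P2(3x3, s1) -> FC1(128) -> FC2(128) -> softmax(2), all valid (no
    padding), with dropout p=0.5 after FC1 and FC2 during training only.
    """

    input_size: int = 208
    conv_kernel: int = 3
    conv_channels: int = 16
    pool_kernel: int = 3
    pool1_stride: int = 2
    pool2_stride: int = 1
    fc_units: int = 128
    dropout_p: float = 0.5
    n_classes: int = 2

    def layer_sizes(self) -> list[int]:
        """Spatial sides after C1, P1, C2, P2 (raises if inconsistent)."""
        s = self.input_size
        s = conv_output_size(s, self.conv_kernel, 1)          # C1
        sizes = [s]
        s = conv_output_size(s, self.pool_kernel, self.pool1_stride)  # P1
        sizes.append(s)
        s = conv_output_size(s, self.conv_kernel, 1)          # C2
        sizes.append(s)
        s = conv_output_size(s, self.pool_kernel, self.pool2_stride)  # P2
        sizes.append(s)
        return sizes

    def validate(self) -> None:
        if self.n_classes != 2:
            raise ParameterError("n_classes must be 2 (target / non-target)")
        if not (0 <= self.dropout_p < 1):
            raise ParameterError(f"dropout_p ({self.dropout_p}) must lie in [0, 1)")
        self.layer_sizes()


class EchoNet:
    """The window classifier: 208x208 gray in, 2 class probabilities out."""

    def __init__(self, config: LocatorConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv1 = _Conv(c.conv_kernel, 1, c.conv_channels, rng)
        self.pool1 = _MaxPool(c.pool_kernel, c.pool1_stride)
        self.conv2 = _Conv(c.conv_kernel, c.conv_channels, c.conv_channels, rng)
        self.pool2 = _MaxPool(c.pool_kernel, c.pool2_stride)
        side = c.layer_sizes()[-1]
        self.flat_dim = side * side * c.conv_channels
        self.fc1 = _Dense(self.flat_dim, c.fc_units, rng)
        self.fc2 = _Dense(c.fc_units, c.fc_units, rng)
        self.out = _Dense(c.fc_units, c.n_classes, rng, relu=False)
        self._layers = [self.conv1, self.conv2, self.fc1, self.fc2, self.out]

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        """uint8 (B,H,W) or (H,W) -> float32 (B,H,W,1) in [-0.5, 0.5].

        Zero-centering keeps roughly half of the randomly initialized
        rectifier units active on both bright and dark inputs, which avoids
        dead-gradient starts on near-constant regions.
        """
        x = np.asarray(images)
        if x.ndim == 2:
            x = x[None]
        x = x.astype(np.float32) / 255.0 - 0.5
        return x[..., None]

    def forward(self, images: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None,
                caches: list[dict] | None = None) -> np.ndarray:
        """Class probabilities, shape (B, n_classes); rows sum to 1."""
        x = self._prepare(images)
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ParameterError(
                f"input spatial size {x.shape[1:3]} != "
                f"{self.config.input_size}")
        cs = caches if caches is not None else [None] * 7
        if caches is not None:
            for i in range(7):
                cs[i] = {}
                caches[i] = cs[i]
        x = self.conv1.forward(x, cs[0])
        x = self.pool1.forward(x, cs[1])
        x = self.conv2.forward(x, cs[2])
        x = self.pool2.forward(x, cs[3])
        x = x.reshape(x.shape[0], -1)
        x = self.fc1.forward(x, cs[4])
        x = self._dropout(x, training, rng, cs[4])
        x = self.fc2.forward(x, cs[5])
        x = self._dropout(x, training, rng, cs[5])
        logits = self.out.forward(x, cs[6])
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def _dropout(self, x, training, rng, cache):
        p = self.config.dropout_p
        if not training or p == 0:
            if cache is not None:
                cache["drop_mask"] = None
            return x
        if rng is None:
            raise ParameterError("training-mode forward needs an rng for dropout")
        mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
        if cache is not None:
            cache["drop_mask"] = mask
        return x * mask

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Inference-mode probabilities, computed in small batches."""
        x = np.asarray(images)
        if x.ndim == 2:
            x = x[None]
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    # -- backward ----------------------------------------------------------

    def backward(self, probs: np.ndarray, labels: np.ndarray,
                 caches: list[dict]) -> None:
        """Accumulate gradients of mean cross-entropy into each layer."""
        b = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(b), labels] -= 1.0
        dlogits /= b
        d = self.out.backward(dlogits.astype(np.float32), caches[6])
        if caches[5]["drop_mask"] is not None:
            d = d * caches[5]["drop_mask"]
        d = self.fc2.backward(d, caches[5])
        if caches[4]["drop_mask"] is not None:
            d = d * caches[4]["drop_mask"]
        d = self.fc1.backward(d, caches[4])
        side = self.config.layer_sizes()[-1]
        d = d.reshape(-1, side, side, self.config.conv_channels)
        d = self.pool2.backward(d, caches[3])
        d = self.conv2.backward(d, caches[2], need_dx=True)
        d = self.pool1.backward(d, caches[1])
        self.conv1.backward(d, caches[0], need_dx=False)

    def sgd_step(self, lr: float, momentum: float = 0.0) -> None:
        for layer in self._layers:
            if momentum > 0.0:
                vW = getattr(layer, "vW", 0.0)
                vb = getattr(layer, "vb", 0.0)
                layer.vW = momentum * vW - lr * layer.dW
                layer.vb = momentum * vb - lr * layer.db
                layer.W += layer.vW
                layer.b += layer.vb
            else:
                layer.W -= lr * layer.dW
                layer.b -= lr * layer.db

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["conv1", "conv2", "fc1", "fc2", "out"]
        state = {}
        for name, layer in zip(names, self._layers):
            state[f"{name}.W"] = layer.W
            state[f"{name}.b"] = layer.b
        return state

    def save(self, path: str | Path) -> None:
        from dataclasses import asdict
        path = Path(path)
        np.savez(path, __config__=json.dumps(asdict(self.config)),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "EchoNet":
        with np.load(Path(path).with_suffix(".npz")
                     if not str(path).endswith(".npz") else path,
                     allow_pickle=False) as data:
            config = LocatorConfig(**json.loads(str(data["__config__"])))
            model = cls(config, seed=0)
            names = ["conv1", "conv2", "fc1", "fc2", "out"]
            for name, layer in zip(names, model._layers):
                layer.W = data[f"{name}.W"].astype(np.float32)
                layer.b = data[f"{name}.b"].astype(np.float32)
        return model
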