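"""Layer objects with explicit forward/backward passes.

Every layer owns its parameters (`params`) and accumulated gradients
(`grads`) as dicts of numpy arrays.  `Sequential` chains layers; models are
serialized with :func:`save_params` / :func:`load_params` (``.npz`` plus a
JSON sidecar written by callers).

Weight initialization is He-normal (std = sqrt(2 / fan_in)) throughout,
drawn from an explicit ``numpy.random.Generator`` so identical seeds give
identical models.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

DTYPE = np.float32


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode

    # weight-decay applies to conv/dense weights only (not biases/norm gains)
    def decayable(self) -> set[str]:
        return {"w"} & set(self.params)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, k=3, stride=1, dilation=1, pad=0,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.dilation, self.pad, self.k = stride, dilation, pad, k
        self.params["w"] = he_normal(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=DTYPE)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x):
        out, self._cache = F.conv2d_forward(
            x, self.params["w"], self.params.get("b"),
            self.stride, self.dilation, self.pad)
        return out

    def backward(self, grad):
        gx, gw, gb = F.conv2d_backward(
            grad, self.params["w"], self._cache,
            self.stride, self.dilation, self.pad, with_bias=self.use_bias)
        self.grads["w"] += gw
        if self.use_bias:
            self.grads["b"] += gb
        return gx


class ConvTranspose2d(Layer):
    """Stride-2 4x4 upsampling block as used by DCGAN generators."""

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad, self.k = stride, pad, k
        self.params["w"] = he_normal(rng, (in_ch, out_ch, k, k), in_ch * k * k)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=DTYPE)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x):
        out, self._cache = F.conv_transpose2d_forward(
            x, self.params["w"], self.params.get("b"), self.stride, self.pad)
        return out

    def backward(self, grad):
        gx, gw, gb = F.conv_transpose2d_backward(
            grad, self.params["w"], self._cache, self.stride, self.pad)
        self.grads["w"] += gw
        if self.use_bias:
            self.grads["b"] += gb
        return gx


class Dense(Layer):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = he_normal(rng, (out_f, in_f), in_f)
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(out_f, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        out = x @ self.params["w"].T
        if self.use_bias:
            out = out + self.params["b"]
        return out

    def backward(self, grad):
        self.grads["w"] += grad.T @ self._x
        if self.use_bias:
            self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["w"]


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(ch, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, grad):
        g, xhat, istd = self.params["gamma"], self._xhat, self._istd
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        if not self.training:
            return grad * (g * istd)[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gxhat = grad * g[None, :, None, None]
        mean_g = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return istd[None, :, None, None] * (gxhat - mean_g - xhat * mean_gx)


class InstanceNorm2d(Layer):
    """Per-sample per-channel normalization with affine parameters."""

    def __init__(self, ch, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(ch, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, grad):
        g, xhat, istd = self.params["gamma"], self._xhat, self._istd
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        gxhat = grad * g[None, :, None, None]
        mean_g = gxhat.mean(axis=(2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return istd * (gxhat - mean_g - xhat * mean_gx)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Swish(Layer):
    """x * sigmoid(x); Swish(0) = 0 so zero inputs stay zero."""

    def forward(self, x):
        self._s = F.sigmoid(x)
        self._x = x
        return x * self._s

    def backward(self, grad):
        s, x = self._s, self._x
        return grad * (s + x * s * (1.0 - s))


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = F.sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(B,C,H,W) -> (B,C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dropout(Layer):
    def __init__(self, p=0.3, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if not self.training or self.p == 0:
            return grad
        return grad * self._mask


class ContextBlock(Layer):
    """Global-context refinement: GAP -> 1x1 linear map (no nonlinearity)
    -> broadcast-add back onto the feature map.

    On a (B,C,1,1) pooled vector a 1x1 convolution is exactly a dense C->C
    map, which is how it is stored here.  Output shape equals input shape.
    """

    def __init__(self, ch, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = he_normal(rng, (ch, ch), ch)
        self.params["b"] = np.zeros(ch, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        if x.shape[2] == 0 or x.shape[3] == 0:
            raise ValueError("context block requires nonzero spatial dims")
        self._x_shape = x.shape
        self._pooled = x.mean(axis=(2, 3))                    # (B, C)
        ctx = self._pooled @ self.params["w"].T + self.params["b"]
        return x + ctx[:, :, None, None]

    def backward(self, grad):
        b, c, h, w = self._x_shape
        gctx = grad.sum(axis=(2, 3))                          # (B, C)
        self.grads["w"] += gctx.T @ self._pooled
        self.grads["b"] += gctx.sum(axis=0)
        gpooled = gctx @ self.params["w"]
        return grad + gpooled[:, :, None, None] / (h * w)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def train(self, mode=True):
        self.training = mode
        for l in self.layers:
            l.train(mode)

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def parameters(self):
        """Yield (layer, name, array, decayable) for every trainable tensor."""
        for l in self.iter_layers():
            for name, arr in l.params.items():
                yield l, name, arr, name in l.decayable()

    def iter_layers(self):
        for l in self.layers:
            if isinstance(l, Sequential):
                yield from l.iter_layers()
            else:
                yield l

    def num_parameters(self) -> int:
        return sum(arr.size for _, _, arr, _ in self.parameters())

    def state_arrays(self):
        """Flat dict of every parameter and norm running stat, for saving."""
        out = {}
        for i, l in enumerate(self.iter_layers()):
            for name, arr in l.params.items():
                out[f"{i}.{name}"] = arr
            if isinstance(l, BatchNorm2d):
                out[f"{i}.running_mean"] = l.running_mean
                out[f"{i}.running_var"] = l.running_var
        return out

    def load_state_arrays(self, arrays):
        for i, l in enumerate(self.iter_layers()):
            for name in l.params:
                l.params[name][...] = arrays[f"{i}.{name}"]
            if isinstance(l, BatchNorm2d):
                l.running_mean[...] = arrays[f"{i}.running_mean"]
                l.running_var[...] = arrays[f"{i}.running_var"]


def save_params(model: Sequential, path):
    np.savez(path, **model.state_arrays())


def load_params(model: Sequential, path):
    with np.load(path) as data:
        model.load_state_arrays(dict(data))
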