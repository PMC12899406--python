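"""Minimal NumPy neural-network core with explicit reverse-mode gradients.

Self-contained layer library used by the scalogram network and the raw-signal
baseline: 2-D convolution (patch matrix + BLAS matmul), batch normalization,
ReLU, max pooling, global average pooling, linear layers, dropout, a softmax
cross-entropy loss, global-norm gradient clipping and an AdamW optimizer.

Image tensors flow in channels-last (B, H, W, C) layout so that patch
extraction and the convolution GEMM touch contiguous memory.  Layers cache
their forward activations and expose ``backward`` returning the input
gradient while accumulating parameter gradients.  All computation is
float32; runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "GlobalAvgPool", "Flatten", "Linear", "Dropout",
    "softmax", "softmax_cross_entropy", "clip_grad_norm", "AdamW",
]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, v in zip(params, state):
            p.value[...] = v

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _patch_matrix(x: np.ndarray, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    """(B, H, W, C) -> (B*Ho*Wo, kh*kw*C) stride-1 patch matrix."""
    b, h, w, c = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    ho, wo = h + 2 * ph - kh + 1, w + 2 * pw - kw + 1
    cols = np.empty((b, ho, wo, kh * kw * c), dtype=np.float32)
    view = cols.reshape(b, ho, wo, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            view[:, :, :, i, j, :] = x[:, i:i + ho, j:j + wo, :]
    return cols.reshape(b * ho * wo, kh * kw * c)


def _conv_nhwc(x: np.ndarray, wmat: np.ndarray, kh: int, kw: int,
               ph: int, pw: int) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlate x (B,H,W,C) with wmat (kh*kw*C, O); returns (y, cols)."""
    b, h, w, _ = x.shape
    ho, wo = h + 2 * ph - kh + 1, w + 2 * pw - kw + 1
    cols = _patch_matrix(x, kh, kw, ph, pw)
    y = cols @ wmat
    return y.reshape(b, ho, wo, wmat.shape[1]), cols


class Conv2d(Module):
    """Stride-1 convolution on (B, H, W, C); default 'same' padding.

    The weight is stored as (out_ch, in_ch, kh, kw); internally a
    (kh*kw*in_ch, out_ch) GEMM matrix is used.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3), pad=None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        if pad is None:
            pad = ((kh - 1) // 2, (kw - 1) // 2)
        self.kernel, self.pad = (kh, kw), tuple(pad)
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kh * kw
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kh, kw)))
        self.bias = Parameter(np.zeros(out_ch))

    def _wmat(self) -> np.ndarray:
        # (O, C, kh, kw) -> (kh*kw*C, O), matching the patch-matrix ordering
        kh, kw = self.kernel
        return np.ascontiguousarray(
            self.weight.value.transpose(2, 3, 1, 0).reshape(kh * kw * self.in_ch,
                                                            self.out_ch))

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        kh, kw = self.kernel
        y, cols = _conv_nhwc(x, self._wmat(), kh, kw, *self.pad)
        self._cols = cols if self.training else None
        return y + self.bias.value

    def backward(self, grad):
        kh, kw = self.kernel
        b, ho, wo, o = grad.shape
        gmat = np.ascontiguousarray(grad, dtype=np.float32).reshape(b * ho * wo, o)
        dwmat = self._cols.T @ gmat  # (kh*kw*C, O)
        self.weight.grad += dwmat.reshape(kh, kw, self.in_ch, o).transpose(3, 2, 0, 1)
        self.bias.grad += gmat.sum(axis=0)
        # input gradient = full correlation with the flipped, transposed kernel
        w_back = self.weight.value[:, :, ::-1, ::-1].transpose(2, 3, 0, 1)
        w_back = np.ascontiguousarray(w_back.reshape(kh * kw * o, self.in_ch))
        dx, _ = _conv_nhwc(grad.astype(np.float32, copy=False), w_back,
                           kh, kw, kh - 1 - self.pad[0], kw - 1 - self.pad[1])
        self._cols = None
        return dx


class BatchNorm2d(Module):
    """Per-channel batch normalization on (B, H, W, C)."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean) * self._invstd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        if not self.training:
            return g * invstd
        gsum = g.sum(axis=(0, 1, 2))
        gxsum = (g * xhat).sum(axis=(0, 1, 2))
        dx = (g - gsum / m - xhat * (gxsum / m)) * invstd
        self._xhat = None
        return dx


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Module):
    """Non-overlapping max pooling on (B, H, W, C)."""

    def __init__(self, pool=(2, 2)):
        self.pool = tuple(pool)

    def forward(self, x):
        b, h, w, c = x.shape
        ph, pw = self.pool
        if h % ph or w % pw:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool {self.pool}")
        ho, wo = h // ph, w // pw
        v = x.reshape(b, ho, ph, wo, pw, c).transpose(0, 1, 3, 5, 2, 4)
        v = np.ascontiguousarray(v).reshape(b, ho, wo, c, ph * pw)
        self._idx = v.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        b, h, w, c = self._inshape
        ph, pw = self.pool
        ho, wo = h // ph, w // pw
        out = np.zeros((b, ho, wo, c, ph * pw), dtype=np.float32)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        out = out.reshape(b, ho, wo, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out).reshape(b, h, w, c)


class GlobalAvgPool(Module):
    """(B, H, W, C) -> (B, C) spatial mean."""

    def forward(self, x):
        self._inshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        b, h, w, c = self._inshape
        g = grad[:, None, None, :] / (h * w)
        return np.broadcast_to(g, (b, h, w, c)).astype(np.float32, copy=True)


class Flatten(Module):
    def forward(self, x):
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._inshape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / d_in)
        self.weight = Parameter(rng.normal(0.0, std, (d_out, d_in)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x):
        self._x = np.ascontiguousarray(x, dtype=np.float32)
        return self._x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dlogits = p.astype(np.float32)
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                              for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class AdamW(Module):
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
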