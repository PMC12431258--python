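"""Neural-network layers on top of the autodiff core.

Conv2d, BatchNorm2d and MaxPool2d carry hand-written numpy kernels for
speed (im2col/col2im for convolution); everything else is composed from
the differentiable primitives in :mod:`snorescreen.nn.core`.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, concat

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "conv1d_channels",
    "GRUDirection",
    "BiGRU",
    "cross_entropy",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container with parameter discovery and train/eval."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        seen = set()
        for mod in self.modules():
            for name, v in mod.__dict__.items():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield f"{type(mod).__name__}.{name}", v

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (name, p) in enumerate(self.named_parameters()):
            state[f"{i:04d}:{name}"] = p.data.copy()
        for j, (mod, name, buf) in enumerate(self._buffers()):
            state[f"buf{j:04d}:{type(mod).__name__}.{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = list(self.named_parameters())
        bufs = list(self._buffers())
        for key, value in state.items():
            if key.startswith("buf"):
                j = int(key[3:7])
                mod, name, _ = bufs[j]
                setattr(mod, name, value.copy())
            else:
                i = int(key.split(":", 1)[0])
                params[i][1].data = value.astype(np.float32, copy=True)

    def _buffers(self):
        for mod in self.modules():
            for name in ("running_mean", "running_var"):
                buf = mod.__dict__.get(name)
                if isinstance(buf, np.ndarray):
                    yield mod, name, buf

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    cols = np.ascontiguousarray(view).reshape(b, c * kh * kw, oh * ow)
    return cols, oh, ow, x.shape


def _col2im(dcols, padded_shape, kh, kw, stride, pad, out_shape):
    b, c, hp, wp = padded_shape
    oh, ow = out_shape
    dx = np.zeros(padded_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i + stride * oh
        for j in range(kw):
            wj = j + stride * ow
            dx[:, :, i:hi:stride, j:wj:stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


class Conv2d(Module):
    """2-D convolution (cross-correlation) with He-normal init, no bias
    (always followed by batch norm in this package)."""

    def __init__(self, c_in, c_out, kernel, stride=1, pad=None, rng=None, bias=False):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        k, s, p = self.kernel, self.stride, self.pad
        cols, oh, ow, padded_shape = _im2col(x.data, k, k, s, p)
        wmat = w.data.reshape(self.c_out, -1)
        out = np.matmul(wmat, cols).reshape(-1, self.c_out, oh, ow)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        bias = self.bias

        def bw(g):
            gmat = g.reshape(g.shape[0], self.c_out, -1)
            w._accumulate(
                np.einsum("boL,bcL->oc", gmat, cols, optimize=True).reshape(
                    w.data.shape
                )
            )
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(wmat.T, gmat)
                x._accumulate(
                    _col2im(dcols, padded_shape, k, k, s, p, (oh, ow))
                )

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._node(out, parents, bw)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def bw(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            gi = g * gamma.data[None, :, None, None]
            if training:
                n = g.shape[0] * g.shape[2] * g.shape[3]
                dxhat = gi
                dx = (
                    dxhat
                    - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) * inv[None, :, None, None]
                del n
            else:
                dx = gi * inv[None, :, None, None]
            x._accumulate(dx)

        return Tensor._node(out, (x, gamma, beta), bw)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Linear(Module):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(d_out,)))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, pad=1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.pad
        data = x.data
        if p:
            data = np.pad(data, ((0, 0), (0, 0), (p, p), (p, p)),
                          constant_values=-np.inf)
        b, c, h, w = data.shape
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        s0, s1, s2, s3 = data.strides
        view = np.lib.stride_tricks.as_strided(
            data, shape=(b, c, oh, ow, k, k),
            strides=(s0, s1, s2 * s, s3 * s, s2, s3),
        ).reshape(b, c, oh, ow, k * k)
        arg = view.argmax(axis=-1)
        out = np.take_along_axis(view, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            if not x.requires_grad:
                return
            dpad = np.zeros((b, c, h, w), dtype=g.dtype)
            ii, jj = np.divmod(arg, k)
            bi, ci, oi, oj = np.indices(arg.shape)
            np.add.at(dpad, (bi, ci, oi * s + ii, oj * s + jj), g)
            if p:
                dpad = dpad[:, :, p : h - p, p : w - p]
            x._accumulate(dpad)

        return Tensor._node(out.copy(), (x,), bw)


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=3).mean(axis=2)


def conv1d_channels(y: Tensor, weight: Tensor) -> Tensor:
    """1-D convolution across the channel axis of (B, C) descriptors.

    ``weight`` has odd length k; zero padding of k//2 keeps the length C.
    """
    k = weight.data.size
    pad = k // 2
    ypad = np.pad(y.data, ((0, 0), (pad, pad)))
    c = y.data.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(ypad, k, axis=1)  # (B, C, k)
    out = windows @ weight.data

    def bw(g):
        weight._accumulate(np.einsum("bc,bck->k", g, windows, optimize=True))
        if y.requires_grad:
            gpad = np.pad(g, ((0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gpad, k, axis=1)
            y._accumulate(gwin @ weight.data[::-1].copy())
        _ = c

    return Tensor._node(out, (y, weight), bw)


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------


class GRUDirection(Module):
    """One direction of a GRU.

    Recurrence (update gate z, reset gate r, candidate c):

        z_t = sigmoid(x_t Wxz + h_{t-1} Whz + bz)
        r_t = sigmoid(x_t Wxr + h_{t-1} Whr + br)
        c_t = tanh(x_t Wxc + r_t * (h_{t-1} Whc) + bc)
        h_t = (1 - z_t) * h_{t-1} + z_t * c_t
    """

    def __init__(self, d_in, hidden, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        bound = 1.0 / np.sqrt(hidden)

        def mk(*shape):
            return Parameter(rng.uniform(-bound, bound, size=shape))

        self.wxz, self.wxr, self.wxc = mk(d_in, hidden), mk(d_in, hidden), mk(d_in, hidden)
        self.whz, self.whr, self.whc = mk(hidden, hidden), mk(hidden, hidden), mk(hidden, hidden)
        self.bz, self.br, self.bc = mk(hidden), mk(hidden), mk(hidden)

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        z = (x_t @ self.wxz + h @ self.whz + self.bz).sigmoid()
        r = (x_t @ self.wxr + h @ self.whr + self.br).sigmoid()
        c = (x_t @ self.wxc + r * (h @ self.whc) + self.bc).tanh()
        return (1.0 - z) * h + z * c

    def run(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        h = Tensor(np.zeros((batch, self.hidden), dtype=xs[0].data.dtype))
        out = []
        for x_t in xs:
            h = self.step(x_t, h)
            out.append(h)
        return out


class BiGRU(Module):
    """Bidirectional GRU over (B, T, d); hidden states concatenated."""

    def __init__(self, d_in, hidden, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = GRUDirection(d_in, hidden, rng)
        self.bwd = GRUDirection(d_in, hidden, rng)

    def forward(self, x: Tensor):
        """Returns (outputs list of T tensors (B, 2h), last_state (B, 2h))."""
        batch, t_len = x.data.shape[0], x.data.shape[1]
        xs = [x.take_time(t, axis=1) for t in range(t_len)]
        hf = self.fwd.run(xs, batch)
        hb = self.bwd.run(xs[::-1], batch)[::-1]
        outs = [concat([f, b], axis=1) for f, b in zip(hf, hb)]
        last = concat([hf[-1], hb[0]], axis=1)
        return outs, last


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (numerically stable)."""
    m = logits.data.max(axis=1, keepdims=True)
    shifted = logits - m
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - lse
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(labels.size), labels] = 1.0
    return -(logp * onehot).sum(axis=1).mean()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
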