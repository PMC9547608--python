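"""A compact CPU convolutional-network library (NumPy, reverse-mode autodiff).

Provides exactly the primitives the fluence-correction architectures need:
2-D convolution and transposed convolution (im2col/col2im backed, BLAS
matmuls), 2x2 max pooling, batch normalization, ReLU/leaky-ReLU, channel
concatenation, elementwise add, and MSE/NRMSE losses, together with an Adam
optimizer.  Tensors build a small dynamic graph; ``Tensor.backward()``
runs reverse-mode accumulation in topological order.

Everything is float32 and deterministic given a seeded ``numpy`` Generator.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------


class Tensor:
    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.grad_fn is not None and t.grad is not None:
                t.grad_fn(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    """(N,C,H,W) -> (N,C,kh,kw,OH,OW) patch view copy."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols


def _col2im(cols, h, w, stride, pad):
    """Scatter-add (N,C,kh,kw,OH,OW) patches back to (N,C,H,W)."""
    n, c, kh, kw, oh, ow = cols.shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride=1, pad=1) -> Tensor:
    o, ci, kh, kw = weight.shape
    cols = _im2col(x.data, kh, kw, stride, pad)
    out = np.tensordot(cols, weight.data, axes=([1, 2, 3], [1, 2, 3]))  # (N,OH,OW,O)
    out = np.moveaxis(out, 3, 1) + bias.data[None, :, None, None]
    out_t = Tensor(out, parents=(x, weight, bias))

    def grad_fn(g):
        bias._accum(g.sum(axis=(0, 2, 3)))
        weight._accum(np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5])))
        dcols = np.tensordot(g, weight.data, axes=([1], [0]))  # (N,OH,OW,Ci,kh,kw)
        dcols = np.moveaxis(dcols, (3, 4, 5), (1, 2, 3))
        x._accum(_col2im(dcols, x.shape[2], x.shape[3], stride, pad))

    out_t.grad_fn = grad_fn
    return out_t


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor, stride=2, pad=0) -> Tensor:
    """Transposed convolution; weight shape (Cin, Cout, kh, kw)."""
    ci, co, kh, kw = weight.shape
    n, _, h, w = x.shape
    oh = (h - 1) * stride - 2 * pad + kh
    ow = (w - 1) * stride - 2 * pad + kw
    cols = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,H,W,Co,kh,kw)
    cols = np.moveaxis(cols, (3, 4, 5), (1, 2, 3))             # (N,Co,kh,kw,H,W)
    out = _col2im(cols, oh, ow, stride, pad) + bias.data[None, :, None, None]
    out_t = Tensor(out, parents=(x, weight, bias))

    def grad_fn(g):
        bias._accum(g.sum(axis=(0, 2, 3)))
        gcols = _im2col(g, kh, kw, stride, pad)                # (N,Co,kh,kw,H,W)
        weight._accum(np.tensordot(x.data, gcols, axes=([0, 2, 3], [0, 4, 5])))
        dx = np.tensordot(gcols, weight.data, axes=([1, 2, 3], [1, 2, 3]))  # (N,H,W,Ci)
        x._accum(np.moveaxis(dx, 3, 1))

    out_t.grad_fn = grad_fn
    return out_t


def maxpool2d(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    x4 = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    x4 = x4.reshape(n, c, h // 2, w // 2, 4)
    arg = x4.argmax(axis=4)
    out = np.take_along_axis(x4, arg[..., None], axis=4)[..., 0]
    out_t = Tensor(out, parents=(x,))

    def grad_fn(g):
        gx = np.zeros_like(x4)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=4)
        gx = gx.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))

    out_t.grad_fn = grad_fn
    return out_t


def relu(x: Tensor, slope: float = 0.0) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)
    out_t = Tensor(out, parents=(x,))
    out_t.grad_fn = lambda g: x._accum(np.where(mask, g, slope * g))
    return out_t


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_t = Tensor(s, parents=(x,))
    out_t.grad_fn = lambda g: x._accum(g * s * (1 - s))
    return out_t


def add(a: Tensor, b: Tensor) -> Tensor:
    out_t = Tensor(a.data + b.data, parents=(a, b))

    def grad_fn(g):
        a._accum(g)
        b._accum(g)

    out_t.grad_fn = grad_fn
    return out_t


def concat(tensors, axis=1) -> Tensor:
    out_t = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                   parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out_t.grad_fn = grad_fn
    return out_t


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running, training: bool,
                momentum=0.1, eps=1e-5) -> Tensor:
    """running = dict with 'mean' and 'var' arrays, updated in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out_t = Tensor(out, parents=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def grad_fn(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            dx = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                  - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
            x._accum(dx * inv[None, :, None, None])
        else:
            x._accum(gxhat * inv[None, :, None, None])

    out_t.grad_fn = grad_fn
    return out_t


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out_t = Tensor(np.mean(diff ** 2), parents=(pred,))
    out_t.grad_fn = lambda g: pred._accum(g * 2 * diff / diff.size)
    return out_t


def nrmse_loss_t(pred: Tensor, target: np.ndarray) -> Tensor:
    """sqrt(mean((y - yhat)^2)) / sqrt(mean(y^2)); target is constant."""
    target = np.asarray(target, dtype=np.float32)
    denom = float(np.sqrt(np.mean(target ** 2)))
    if denom == 0:
        raise ValueError("NRMSE undefined for an all-zero reference")
    diff = pred.data - target
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    out_t = Tensor(rmse / denom, parents=(pred,))

    def grad_fn(g):
        if rmse == 0:
            return
        pred._accum(g * diff / (diff.size * rmse * denom))

    out_t.grad_fn = grad_fn
    return out_t


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    def state_arrays(self):
        """Flat list of arrays capturing the module state (weights + BN stats)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running["mean"], m.running["var"]])
        return arrays

    def load_state_arrays(self, arrays):
        arrays = list(arrays)
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            p.data = np.asarray(a, dtype=np.float32).reshape(p.data.shape)
        rest = arrays[len(params):]
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running["mean"] = np.asarray(rest[i], dtype=np.float32)
                m.running["var"] = np.asarray(rest[i + 1], dtype=np.float32)
                i += 2


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None):
        pad = k // 2 if pad is None else pad
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0, scale, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k=2, stride=2, pad=0, rng=None):
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0, scale, (cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running = {"mean": np.zeros(c, dtype=np.float32),
                        "var": np.ones(c, dtype=np.float32)}
        self.training = True

    def __call__(self, x):
        return batchnorm2d(x, self.gamma, self.beta, self.running, self.training)


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
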