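"""Minimal reverse-mode autodiff and CNN building blocks on numpy.

The package trains small encoder-decoder depth networks and PatchGAN
discriminators on the CPU; this module provides the required machinery:
a :class:`Tensor` with a dynamically built computation graph, 2-D
convolution via im2col, batch normalization with switchable batch/running
statistics, pixel-shuffle upsampling, bilinear interpolation as a linear
operator, and an Adam optimizer.  Everything is float64 and deterministic
given an explicit seed.

Gradient correctness of every primitive is pinned by central-difference
checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "concat",
    "conv2d", "pixel_shuffle", "upsample_bilinear", "upsample_nearest",
    "Module", "Conv2d", "BatchNorm2d", "Parameter",
    "Adam", "grad_check",
]


# ---------------------------------------------------------------------------
# Tensor and graph
# ---------------------------------------------------------------------------

class Tensor:
    """An n-d array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:  # keep float32 (training speed); else f64
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- graph mechanics ----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (default seed gradient 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        return _unary(self, lambda a: a ** p, lambda g, a, out: g * p * a ** (p - 1))

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            a, b = self, other

            def bwd(g):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)
            out._backward, out._parents = bwd, (a, other)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            src = self

            def bwd(g):
                full = np.zeros_like(src.data)
                np.add.at(full, idx, g)
                src._accumulate(full)
            out._backward, out._parents = bwd, (src,)
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self):
        return _unary(self, lambda a: np.maximum(a, 0.0),
                      lambda g, a, out: g * (a > 0))

    def leaky_relu(self, slope: float = 0.2):
        return _unary(self, lambda a: np.where(a > 0, a, slope * a),
                      lambda g, a, out: g * np.where(a > 0, 1.0, slope))

    def sigmoid(self):
        return _unary(self, lambda a: 1.0 / (1.0 + np.exp(-a)),
                      lambda g, a, out: g * out * (1.0 - out))

    def softplus(self):
        # numerically stable log(1 + e^x)
        return _unary(self, lambda a: np.logaddexp(0.0, a),
                      lambda g, a, out: g / (1.0 + np.exp(-a)))

    def tanh(self):
        return _unary(self, np.tanh, lambda g, a, out: g * (1.0 - out * out))

    def tan(self):
        return _unary(self, np.tan, lambda g, a, out: g * (1.0 + out * out))

    def log(self):
        return _unary(self, np.log, lambda g, a, out: g / a)

    def exp(self):
        return _unary(self, np.exp, lambda g, a, out: g * out)

    def sqrt(self):
        return _unary(self, np.sqrt, lambda g, a, out: g * 0.5 / out)

    def abs(self):
        return _unary(self, np.abs, lambda g, a, out: g * np.sign(a))

    def clamp(self, lo: float, hi: float):
        return _unary(self, lambda a: np.clip(a, lo, hi),
                      lambda g, a, out: g * ((a > lo) & (a < hi)))

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            src, shape = self, self.data.shape

            def bwd(g):
                if axis is None:
                    src._accumulate(np.broadcast_to(g, shape))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    src._accumulate(np.broadcast_to(gg, shape))
            out._backward, out._parents = bwd, (src,)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            src, orig = self, self.data.shape
            out._backward = lambda g: src._accumulate(g.reshape(orig))
            out._parents = (src,)
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad)
        if out.requires_grad:
            src = self
            inv = np.argsort(axes)
            out._backward = lambda g: src._accumulate(g.transpose(*inv))
            out._parents = (src,)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad)
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))
        out._backward, out._parents = bwd, (a, b)
    return out


def _unary(a: Tensor, fwd, bwd) -> Tensor:
    out = Tensor(fwd(a.data), a.requires_grad)
    if out.requires_grad:
        out._backward = lambda g: a._accumulate(bwd(g, a.data, out.data))
        out._parents = (a,)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward, out._parents = bwd, tuple(tensors)
    return out


# ---------------------------------------------------------------------------
# Spatial primitives
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW input via im2col + GEMM."""
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = weight.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N, C, Ho, Wo, kh, kw)
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                               ).reshape(N * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(Cout, C * kh * kw)
    out_flat = col @ wmat.T
    if bias is not None:
        out_flat += bias.data
    out_data = out_flat.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    out = Tensor(out_data, req)
    if req:
        parents = (x, weight) if bias is None else (x, weight, bias)

        def bwd(g):
            gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)
                                      ).reshape(N * Ho * Wo, Cout)
            if weight.requires_grad:
                weight._accumulate((gf.T @ col).reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gf.sum(axis=0))
            if x.requires_grad:
                dcol = (gf @ wmat).reshape(N, Ho, Wo, C, kh, kw)
                dcol = dcol.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, kh, kw)
                dxp = np.zeros((N, C, Hp, Wp), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += dcol[:, :, :, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(dxp)
        out._backward, out._parents = bwd, parents
    return out


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r).

    Output channel c at offset (di, dj) reads input channel c*r^2 + di*r + dj,
    the layout the ICNR initializer in :mod:`depth_net` assumes.
    """
    N, Crr, H, W = x.data.shape
    if Crr % (r * r):
        raise ValueError("channel count not divisible by r^2")
    C = Crr // (r * r)
    out_data = x.data.reshape(N, C, r, r, H, W).transpose(
        0, 1, 4, 2, 5, 3).reshape(N, C, H * r, W * r)
    out = Tensor(out_data, x.requires_grad)
    if out.requires_grad:
        def bwd(g):
            gg = g.reshape(N, C, H, r, W, r).transpose(
                0, 1, 3, 5, 2, 4).reshape(N, Crr, H, W)
            x._accumulate(gg)
        out._backward, out._parents = bwd, (x,)
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, align_corners=False."""
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(math.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        w = src - i0
        A[o, i0] += 1.0 - w
        A[o, i1] += w
    return A


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of the trailing two axes (NCHW or HW), upscale only."""
    Hi, Wi = x.data.shape[-2], x.data.shape[-1]
    Ho, Wo = size
    if Ho < Hi or Wo < Wi:
        raise ValueError("upsample_bilinear only upscales")
    A = _interp_matrix(Ho, Hi).astype(x.data.dtype)
    B = _interp_matrix(Wo, Wi).astype(x.data.dtype)
    out_data = np.einsum("oi,...ij,pj->...op", A, x.data, B, optimize=True)
    out = Tensor(out_data, x.requires_grad)
    if out.requires_grad:
        def bwd(g):
            x._accumulate(np.einsum("oi,...op,pj->...ij", A, g, B,
                                    optimize=True))
        out._backward, out._parents = bwd, (x,)
    return out


def upsample_nearest(x: Tensor, r: int) -> Tensor:
    out_data = x.data.repeat(r, axis=-2).repeat(r, axis=-1)
    out = Tensor(out_data, x.requires_grad)
    if out.requires_grad:
        H, W = x.data.shape[-2], x.data.shape[-1]

        def bwd(g):
            gg = g.reshape(*g.shape[:-2], H, r, W, r).sum(axis=(-3, -1))
            x._accumulate(gg)
        out._backward, out._parents = bwd, (x,)
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def Parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Parameter container with train/eval mode, in the familiar style."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                # Tensors on modules are parameters (possibly frozen);
                # buffers are plain ndarrays.
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def param_dtype(self):
        for _, p in self.named_parameters():
            return p.data.dtype
        return np.float64

    def to_dtype(self, dtype) -> "Module":
        """Cast all parameters and buffers (float32 speeds CPU training)."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k, v in list(m.__dict__.items()):
                if isinstance(v, np.ndarray):
                    setattr(m, k, v.astype(dtype))
        return self

    # -- flat state for checkpoints and checksums ---------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                params[key].data = np.array(value, dtype=params[key].data.dtype)
            elif key in bufs:
                bufs[key][...] = value
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def named_buffers(self, prefix: str = "") -> Iterable[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def checksum(self) -> float:
        """Order-stable scalar digest of all parameters and buffers."""
        total = 0.0
        for name, arr in sorted(self.state_dict().items()):
            total += float(np.sum(arr * np.arange(1, arr.size + 1).reshape(arr.shape)))
        return total


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        # He-uniform, appropriate for the ReLU family used throughout
        bound = math.sqrt(6.0 / fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    In training mode batch statistics are used and the running estimates
    updated; in eval mode (or when ``stats_frozen``) the running estimates
    are used and never touched — the contract required of both encoders
    during adversarial adaptation.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self.stats_frozen = False

    def __call__(self, x: Tensor) -> Tensor:
        use_batch = self.training and not self.stats_frozen
        if use_batch:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat_data = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]

        gamma, beta = self.gamma, self.beta
        out_data = gamma.data[None, :, None, None] * xhat_data \
            + beta.data[None, :, None, None]
        req = x.requires_grad or gamma.requires_grad or beta.requires_grad
        out = Tensor(out_data, req)
        if req:
            def bwd(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat_data).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gs = g * gamma.data[None, :, None, None]
                    if use_batch:
                        m = g.shape[0] * g.shape[2] * g.shape[3]
                        term = gs - gs.mean(axis=(0, 2, 3), keepdims=True) \
                            - xhat_data * (gs * xhat_data).mean(axis=(0, 2, 3),
                                                                keepdims=True)
                        x._accumulate(term * inv_std[None, :, None, None])
                        del m
                    else:
                        x._accumulate(gs * inv_std[None, :, None, None])
            out._backward, out._parents = bwd, (x, gamma, beta)
        return out


class Adam(Module):
    """Adam with optional per-element gradient value clipping."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float | None = None):
        super().__init__()
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.grad_clip is not None:
                g = np.clip(g, -self.grad_clip, self.grad_clip)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Verification helper
# ---------------------------------------------------------------------------

def grad_check(fn: Callable[[Tensor], Tensor], x: np.ndarray,
               eps: float = 1e-5) -> float:
    """Max abs deviation between autodiff and central-difference gradients."""
    t = Tensor(x, requires_grad=True)
    fn(t).backward()
    analytic = t.grad.copy()
    numeric = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(fn(Tensor(x)).data)
        flat[i] = orig - eps
        lo = float(fn(Tensor(x)).data)
        flat[i] = orig
        numeric.reshape(-1)[i] = (hi - lo) / (2 * eps)
    return float(np.max(np.abs(analytic - numeric)))
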