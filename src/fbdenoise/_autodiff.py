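"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core used by the network builders in
:mod:`fbdenoise.models`.  It implements exactly the operations the
denoising pipeline needs -- 3x3 ``same`` convolution, ReLU, 2x2 max
pooling, 2x bilinear upsampling, channel concatenation, fully connected
layers (including layers whose weight matrices are themselves computed
tensors, as required by the hypernetwork quality head), pixel gathering
and mean-squared-error losses -- together with an Adam optimizer.

Conventions
-----------
Image tensors are channel-first ``(C, H, W)`` float32 arrays without a
batch axis; the per-image training loop never batches.  Vectors are 1-D,
weight matrices 2-D.  Gradients are accumulated in ``Tensor.grad`` by
:func:`backward` via a topological sweep of the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "backward",
    "conv2d",
    "relu",
    "leaky_relu",
    "abs_",
    "square",
    "max_pool2",
    "upsample_bilinear2",
    "concat_channels",
    "add",
    "scale",
    "linear",
    "narrow",
    "reshape",
    "global_avg_pool",
    "gather_pixels",
    "pad_reflect",
    "crop",
    "tv2d",
    "mse_to",
    "Adam",
]


class Tensor:
    """A node in the computation tape: value, gradient slot and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data.item())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data):
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def constant(data):
    """A non-trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float32))


def _needs_grad(*tensors):
    return any(t.requires_grad for t in tensors)


def _node(data, parents, backward_fn):
    req = _needs_grad(*parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward_fn if req else None)


def _accum(t, g):
    """Accumulate gradient ``g`` into ``t.grad`` (defensive copy)."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _accum_owned(t, g):
    """Accumulate a gradient buffer freshly allocated by the caller.

    Skips the defensive copy of :func:`_accum`; only safe when ``g`` is
    not referenced anywhere else.
    """
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if g.dtype == np.float32 else g.astype(np.float32)
    else:
        t.grad += g


def backward(loss):
    """Backpropagate from a scalar ``loss`` through the recorded tape."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    order = []
    seen = set()
    stack = [(loss, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x, k):
    """(C,H,W) zero-padded -> (C*k*k, H*W) patch matrix for stride-1 same conv.

    Row ordering is channel-major then kernel-position, matching
    ``w.reshape(Cout, Cin*k*k)``, so the convolution is a single matmul
    with no transposed copies.
    """
    c, h, w = x.shape
    p = k // 2
    xp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    xp[:, p:p + h, p:p + w] = x
    cols = np.empty((c, k * k, h, w), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, ki * k + kj] = xp[:, ki:ki + h, kj:kj + w]
    return cols.reshape(c * k * k, h * w)


def conv2d(x, w, b):
    """Stride-1 zero-padded ("same") 2-D convolution.

    ``x``: (Cin,H,W); ``w``: (Cout,Cin,k,k) with odd k; ``b``: (Cout,).
    Output (Cout,H,W) matches the input spatial shape, so fully
    convolutional stacks preserve geometry and U-Net skips concatenate
    without cropping.
    """
    cin, h, wd = x.shape
    cout, cin_w, k, k2 = w.shape
    if cin_w != cin or k != k2 or k % 2 == 0:
        raise ValueError("weight shape incompatible with input")
    cols = _im2col(x.data, k)                       # (Cin*k*k, HW)
    wm = w.data.reshape(cout, -1)                   # (Cout, Cin*k*k)
    out = wm @ cols
    out += b.data[:, None]
    out = out.reshape(cout, h, wd)

    def bwd(g):
        gm = g.reshape(cout, h * wd)
        if w.requires_grad:
            _accum_owned(w, (gm @ cols.T).reshape(w.data.shape))
        if b.requires_grad:
            _accum_owned(b, gm.sum(axis=1))
        if x.requires_grad:
            # dL/dx is a full correlation: convolve g with spatially
            # flipped kernels, channels transposed.
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
            gcols = _im2col(gm.reshape(cout, h, wd), k)
            _accum_owned(x, (wflip.reshape(cin, -1) @ gcols).reshape(cin, h, wd))

    return _node(out, (x, w, b), bwd)


# ---------------------------------------------------------------------------
# pointwise nonlinearities


def relu(x):
    out = np.maximum(x.data, 0.0)

    def bwd(g):
        _accum_owned(x, g * (x.data > 0))

    return _node(out, (x,), bwd)


def leaky_relu(x, slope=0.1):
    out = np.where(x.data > 0, x.data, np.float32(slope) * x.data)

    def bwd(g):
        _accum_owned(x, np.where(x.data > 0, g, np.float32(slope) * g))

    return _node(out, (x,), bwd)


def square(x):
    out = x.data * x.data

    def bwd(g):
        _accum_owned(x, 2.0 * x.data * g)

    return _node(out, (x,), bwd)


def abs_(x):
    """|x|; subgradient 0 at the kink.  Enforces noise-map nonnegativity."""
    out = np.abs(x.data)

    def bwd(g):
        _accum_owned(x, g * np.sign(x.data))

    return _node(out, (x,), bwd)


# ---------------------------------------------------------------------------
# spatial resampling


def max_pool2(x):
    """2x2 max pooling, stride 2; requires even H and W."""
    c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2 needs even spatial dims")
    x4 = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    x4 = x4.reshape(c, h // 2, w // 2, 4)
    idx = x4.argmax(axis=-1)
    out = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        g4 = np.zeros((c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = g4.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        _accum_owned(x, np.ascontiguousarray(gx).reshape(c, h, w))

    return _node(out, (x,), bwd)


def _up_axis(a, axis):
    """Double the length along ``axis`` with 2x bilinear interpolation.

    Output sample centres sit at input coordinates (o+0.5)/2 - 0.5, the
    convention that keeps the image extent fixed (align_corners=False):
    even outputs mix 0.75*x[i] + 0.25*x[i-1], odd 0.75*x[i] + 0.25*x[i+1],
    clamped at the borders.
    """
    n = a.shape[axis]
    i = np.arange(2 * n) // 2
    j = np.clip(np.where(np.arange(2 * n) % 2 == 0, i - 1, i + 1), 0, n - 1)
    return 0.75 * np.take(a, i, axis=axis) + 0.25 * np.take(a, j, axis=axis)


def _up_axis_T(g, axis):
    """Transpose (adjoint) of :func:`_up_axis`: (2n -> n) along ``axis``."""
    g = np.moveaxis(g, axis, 0)
    n = g.shape[0] // 2
    out = 0.75 * (g[0::2] + g[1::2])
    # even output 2i contributed 0.25 to i-1 (clamped to 0)
    out[:-1] += 0.25 * g[2::2]
    out[0] += 0.25 * g[0]
    # odd output 2i+1 contributed 0.25 to i+1 (clamped to n-1)
    out[1:] += 0.25 * g[1:-1:2]
    out[-1] += 0.25 * g[-1]
    return np.moveaxis(out, 0, axis)


def upsample_bilinear2(x):
    """Bilinear 2x spatial upsampling of a (C,H,W) tensor."""
    out = _up_axis(_up_axis(x.data, 1), 2)

    def bwd(g):
        _accum_owned(x, _up_axis_T(_up_axis_T(g, 2), 1))

    return _node(out, (x,), bwd)


# ---------------------------------------------------------------------------
# structural ops


def concat_channels(parts):
    """Concatenate (Ci,H,W) tensors along the channel axis."""
    out = np.concatenate([p.data for p in parts], axis=0)
    splits = np.cumsum([p.shape[0] for p in parts])[:-1]

    def bwd(g):
        for p, gp in zip(parts, np.split(g, splits, axis=0)):
            _accum(p, gp)

    return _node(out, tuple(parts), bwd)


def add(a, b):
    out = a.data + b.data

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return _node(out, (a, b), bwd)


def scale(x, s):
    s = float(s)
    out = x.data * s

    def bwd(g):
        _accum(x, g * s)

    return _node(out, (x,), bwd)


def linear(x, w, b=None):
    """w @ x (+ b) for a 1-D input vector; w may itself be a computed tensor."""
    out = w.data @ x.data
    if b is not None:
        out = out + b.data

    def bwd(g):
        if w.requires_grad:
            _accum(w, np.outer(g, x.data))
        if b is not None and b.requires_grad:
            _accum(b, g)
        if x.requires_grad:
            _accum(x, w.data.T @ g)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bwd)


def narrow(x, start, length):
    """Slice [start, start+length) of a 1-D tensor."""
    out = x.data[start:start + length]

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[start:start + length] = g
        _accum(x, gx)

    return _node(out, (x,), bwd)


def reshape(x, shape):
    out = x.data.reshape(shape)

    def bwd(g):
        _accum(x, g.reshape(x.data.shape))

    return _node(out, (x,), bwd)


def global_avg_pool(x):
    """(C,H,W) -> (C,) mean over the spatial axes."""
    c, h, w = x.shape
    out = x.data.mean(axis=(1, 2))

    def bwd(g):
        _accum(x, np.broadcast_to(g[:, None, None] / (h * w), x.data.shape).astype(np.float32))

    return _node(out, (x,), bwd)


def gather_pixels(x, rows, cols):
    """Pick x[0, rows, cols] from a single-channel (1,H,W) tensor -> (n,)."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    out = x.data[0, rows, cols]

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx[0], (rows, cols), g)
        _accum(x, gx)

    return _node(out, (x,), bwd)


def mse_to(x, target):
    """Mean squared error of a tensor against a constant array -> scalar."""
    target = np.asarray(target, dtype=np.float32)
    diff = x.data - target
    out = np.float32(np.mean(diff ** 2))

    def bwd(g):
        _accum(x, (2.0 / diff.size) * diff * g)

    return _node(out, (x,), bwd)


def tv2d(x):
    """Mean squared forward difference of a (C,H,W) tensor -> scalar.

    A smooth total-variation-style roughness penalty.
    """
    dh = x.data[:, 1:, :] - x.data[:, :-1, :]
    dw = x.data[:, :, 1:] - x.data[:, :, :-1]
    n = dh.size + dw.size
    out = np.float32((np.sum(dh ** 2) + np.sum(dw ** 2)) / n)

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, 1:, :] += 2.0 * dh
        gx[:, :-1, :] -= 2.0 * dh
        gx[:, :, 1:] += 2.0 * dw
        gx[:, :, :-1] -= 2.0 * dw
        _accum(x, (g / n) * gx)

    return _node(out, (x,), bwd)


def pad_reflect(x, pad_h, pad_w):
    """Reflect-pad the two trailing (spatial) axes of a (C,H,W) tensor.

    ``pad_h``/``pad_w`` are (before, after) pairs.  Backward scatter-adds
    each output gradient onto its reflected source pixel.
    """
    c, h, w = x.shape
    (ht, hb), (wl, wr) = pad_h, pad_w
    ridx = np.pad(np.arange(h), (ht, hb), mode="reflect")
    cidx = np.pad(np.arange(w), (wl, wr), mode="reflect")
    out = x.data[:, ridx][:, :, cidx]

    def bwd(g):
        gx = np.zeros_like(x.data)
        rr, cc = np.meshgrid(ridx, cidx, indexing="ij")
        for ch in range(c):
            np.add.at(gx[ch], (rr, cc), g[ch])
        _accum(x, gx)

    return _node(out, (x,), bwd)


def crop(x, h, w):
    """Keep the top-left (h, w) window of a (C,H,W) tensor."""
    out = x.data[:, :h, :w]

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, :h, :w] = g
        _accum(x, gx)

    return _node(out, (x,), bwd)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
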