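"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the tensor substrate for the sequence models in
:mod:`phosphodia.neural_model`: a tape of primitive operations (matmul,
elementwise arithmetic, gather, softmax, layer norm, ...) with hand-written
vector-Jacobian products, plus an Adam optimizer.  It is deliberately small
— float64 throughout, CPU only, no graph optimization — and every gradient
is covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack", "lstm_seq"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def _acc(self, g):
        """Accumulate a gradient contribution (lazily allocated)."""
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def detach(self):
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -------------------------------------------------------------- operators
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._acc(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._acc(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ elementwise
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(g * (self.data > 0.0))

        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._acc(np.swapaxes(g, a, b))

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._acc(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ---------------------------------------------------------- fused kernels
    def softmax_last(self, additive_mask: np.ndarray | None = None):
        """Softmax over the last axis, optionally after adding a mask of
        0 / -inf entries (pad positions get -inf and zero probability)."""
        x = self.data
        if additive_mask is not None:
            x = x + additive_mask
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=-1, keepdims=True)
                self._acc(y * (g - dot))

        out._backward = bwd
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with learned gain/bias."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gain.data + bias.data, parents=(self, gain, bias))
        d = x.shape[-1]

        def bwd(g):
            if gain.requires_grad:
                gain._acc(_unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad:
                bias._acc(_unbroadcast(g, bias.data.shape))
            if self.requires_grad:
                gx = g * gain.data
                t1 = gx - gx.mean(axis=-1, keepdims=True)
                t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                self._acc(inv * (t1 - t2))
            _ = d

        out._backward = bwd
        return out

    def gather_rows(self, ids: np.ndarray):
        """Embedding lookup: rows of a (V, d) table by an integer array."""
        out = Tensor(self.data[ids], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, ids, g)

        out._backward = bwd
        return out


def lstm_seq(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """Run a full unidirectional LSTM over (batch, time, features).

    A single fused tape node: the forward loop stores per-step activations
    and the backward pass is classic truncated-free BPTT.  Gate layout in
    the 4H axis is [input, forget, cell, output]; the forget-gate bias is
    expected to be pre-initialized by the caller.
    """
    X, Wx, Wh, B_ = x.data, wx.data, wh.data, b.data
    nb, T, _ = X.shape
    H = Wh.shape[0]
    xw = X @ Wx  # (B, T, 4H), one big matmul
    h = np.zeros((nb, H))
    c = np.zeros((nb, H))
    I = np.empty((T, nb, H)); F = np.empty((T, nb, H))
    G = np.empty((T, nb, H)); O = np.empty((T, nb, H))
    C = np.empty((T, nb, H)); TC = np.empty((T, nb, H))
    Hs = np.empty((T, nb, H))
    for t in range(T):
        z = xw[:, t] + h @ Wh + B_
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        I[t], F[t], G[t], O[t], C[t], TC[t], Hs[t] = i, f, g, o, c, tc, h
    out = Tensor(np.swapaxes(Hs, 0, 1).copy(), parents=(x, wx, wh, b))

    def bwd(grad):
        dH = np.swapaxes(grad, 0, 1)  # (T, B, H)
        dZ = np.empty((T, nb, 4 * H))
        dh = np.zeros((nb, H))
        dc = np.zeros((nb, H))
        for t in range(T - 1, -1, -1):
            dht = dH[t] + dh
            i, f, g, o, ct, tc = I[t], F[t], G[t], O[t], C[t], TC[t]
            do = dht * tc
            dct = dc + dht * o * (1.0 - tc * tc)
            di = dct * g
            dg = dct * i
            df = dct * (C[t - 1] if t > 0 else 0.0)
            dc = dct * f
            dz = dZ[t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh = dz @ Wh.T
        dZbt = np.swapaxes(dZ, 0, 1)  # (B, T, 4H)
        if x.requires_grad:
            x._acc(dZbt @ Wx.T)
        if wx.requires_grad:
            D = X.shape[-1]
            wx._acc(X.reshape(-1, D).T @ dZbt.reshape(-1, 4 * H))
        if wh.requires_grad:
            Hprev = np.concatenate([np.zeros((1, nb, H)), Hs[:-1]], axis=0)
            wh._acc(Hprev.reshape(-1, H).T @ dZ.reshape(-1, 4 * H))
        if b.requires_grad:
            b._acc(dZ.sum(axis=(0, 1)))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._acc(g[tuple(idx)])

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, k, axis=axis))

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer with an adjustable learning rate (for step decay)."""

    def __init__(self, params: list[Tensor], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
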