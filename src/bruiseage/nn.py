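"""Small CPU neural-network engine: layers with exact backprop, plus Adam.

Implemented from scratch on numpy so the spectral-spatial regressor trains
and differentiates (including gradients with respect to the *input*, needed
for saliency-based band attribution) without any deep-learning framework.

Conventions:

* float32 everywhere;
* channels-last activations — ``(rows, L, C)`` for 1-D stages and
  ``(N, H, W, C)`` for 2-D stages — so convolutions reduce to one im2col
  copy plus one large matrix multiply;
* every layer caches what its backward pass needs; ``backward`` consumes the
  cache of the most recent ``forward``;
* ``need_param_grads=False`` skips weight-gradient work when only the input
  gradient is wanted (saliency).

All layers are deterministic; stochastic layers (dropout) draw from an
explicitly supplied ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg.blas import sgemm

try:  # fast single-thread kernels for the hot spectral-stage loops
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


F32 = np.float32


@njit(fastmath=True)
def _nb_conv1d_fwd(x, W, b, pad):
    """Direct same-length 1-D convolution: x (R, L, C) * W (K, C, O) + b.

    The accumulator for each output position stays in registers/L1; the
    output array is written exactly once.
    """
    R, L, C = x.shape
    K, _, O = W.shape
    y = np.empty((R, L, O), dtype=x.dtype)
    acc = np.empty(O, dtype=x.dtype)
    for r in range(R):
        for l in range(L):
            for o in range(O):
                acc[o] = b[o]
            t0 = max(0, pad - l)
            t1 = min(K, L + pad - l)
            for t in range(t0, t1):
                j = l + t - pad
                for c in range(C):
                    xv = x[r, j, c]
                    for o in range(O):
                        acc[o] += xv * W[t, c, o]
            for o in range(O):
                y[r, l, o] = acc[o]
    return y


@njit(fastmath=True)
def _nb_conv1d_bwd(x, W, g, pad, need_param_grads):
    R, L, C = x.shape
    K, _, O = W.shape
    gx = np.empty_like(x)
    gW = np.zeros_like(W)
    gb = np.zeros(O, dtype=x.dtype)
    # input gradient: gather over the output positions each input feeds
    acc = np.empty(C, dtype=x.dtype)
    for r in range(R):
        for j in range(L):
            for c in range(C):
                acc[c] = 0.0
            t0 = max(0, pad - (L - 1 - j))
            t1 = min(K, j + pad + 1)
            for t in range(t0, t1):
                l = j + pad - t
                for c in range(C):
                    s = np.float32(0.0)
                    for o in range(O):
                        s += g[r, l, o] * W[t, c, o]
                    acc[c] += s
            for c in range(C):
                gx[r, j, c] = acc[c]
    if need_param_grads:
        # weight/bias gradients in a second pass; gW is tiny and L1-resident
        for r in range(R):
            for l in range(L):
                for o in range(O):
                    gb[o] += g[r, l, o]
                t0 = max(0, pad - l)
                t1 = min(K, L + pad - l)
                for t in range(t0, t1):
                    j = l + t - pad
                    for c in range(C):
                        xv = x[r, j, c]
                        for o in range(O):
                            gW[t, c, o] += xv * g[r, l, o]
    return gx, gW, gb


@njit(fastmath=True)
def _nb_conv1d_fwd_o4(x, W, b, pad):
    """O == 4 specialization of the 1-D convolution (scalar registers).

    Positions whose kernel window lies fully inside the sequence (the vast
    majority) run a branch-free inner loop with fixed trip counts.
    """
    R, L, C = x.shape
    K = W.shape[0]
    y = np.empty((R, L, 4), dtype=x.dtype)
    b0, b1, b2, b3 = b[0], b[1], b[2], b[3]
    mid_lo = pad
    mid_hi = L + pad - K + 1  # l < mid_hi -> all K taps valid
    for r in range(R):
        for l in range(L):
            a0 = b0
            a1 = b1
            a2 = b2
            a3 = b3
            if mid_lo <= l < mid_hi:
                base = l - pad
                for t in range(K):
                    j = base + t
                    for c in range(C):
                        xv = x[r, j, c]
                        a0 += xv * W[t, c, 0]
                        a1 += xv * W[t, c, 1]
                        a2 += xv * W[t, c, 2]
                        a3 += xv * W[t, c, 3]
            else:
                t0 = max(0, pad - l)
                t1 = min(K, L + pad - l)
                for t in range(t0, t1):
                    j = l + t - pad
                    for c in range(C):
                        xv = x[r, j, c]
                        a0 += xv * W[t, c, 0]
                        a1 += xv * W[t, c, 1]
                        a2 += xv * W[t, c, 2]
                        a3 += xv * W[t, c, 3]
            y[r, l, 0] = a0
            y[r, l, 1] = a1
            y[r, l, 2] = a2
            y[r, l, 3] = a3
    return y


@njit(fastmath=True)
def _nb_conv1d_bwd_gx_c4(W, g, pad, length):
    """C == 4 specialization of the input-gradient pass."""
    R, L, O = g.shape
    K = W.shape[0]
    gx = np.empty((R, length, 4), dtype=g.dtype)
    for r in range(R):
        for j in range(length):
            a0 = np.float32(0.0)
            a1 = np.float32(0.0)
            a2 = np.float32(0.0)
            a3 = np.float32(0.0)
            t0 = max(0, pad - (length - 1 - j))
            t1 = min(K, j + pad + 1)
            for t in range(t0, t1):
                l = j + pad - t
                for o in range(O):
                    gv = g[r, l, o]
                    a0 += gv * W[t, 0, o]
                    a1 += gv * W[t, 1, o]
                    a2 += gv * W[t, 2, o]
                    a3 += gv * W[t, 3, o]
            gx[r, j, 0] = a0
            gx[r, j, 1] = a1
            gx[r, j, 2] = a2
            gx[r, j, 3] = a3
    return gx


@njit(fastmath=True)
def _nb_conv1d_bwd_params(x, g, pad, K):
    """Weight/bias gradients: gW (K, C, O) and gb (O)."""
    R, L, C = x.shape
    O = g.shape[2]
    gW = np.zeros((K, C, O), dtype=x.dtype)
    gb = np.zeros(O, dtype=x.dtype)
    for r in range(R):
        for l in range(L):
            for o in range(O):
                gb[o] += g[r, l, o]
            t0 = max(0, pad - l)
            t1 = min(K, L + pad - l)
            for t in range(t0, t1):
                j = l + t - pad
                for c in range(C):
                    xv = x[r, j, c]
                    for o in range(O):
                        gW[t, c, o] += xv * g[r, l, o]
    return gW, gb


@njit(fastmath=True)
def _nb_bn_fwd_train(x2, mean, inv_std, gamma, beta):
    """One-pass batch-norm transform: returns (xhat, y)."""
    M, C = x2.shape
    xhat = np.empty_like(x2)
    y = np.empty_like(x2)
    for i in range(M):
        for c in range(C):
            h = (x2[i, c] - mean[c]) * inv_std[c]
            xhat[i, c] = h
            y[i, c] = gamma[c] * h + beta[c]
    return xhat, y


@njit(fastmath=True)
def _nb_bn_bwd_train(g2, xhat, gamma, inv_std, m1, m2):
    """One-pass training-mode batch-norm input gradient."""
    M, C = g2.shape
    gx = np.empty_like(g2)
    for i in range(M):
        for c in range(C):
            gx[i, c] = inv_std[c] * (gamma[c] * g2[i, c] - m1[c] - xhat[i, c] * m2[c])
    return gx


@njit(fastmath=True)
def _nb_colsums(x2):
    """Per-column sum and sum of squares in one pass: x2 (M, C)."""
    M, C = x2.shape
    s = np.zeros(C, dtype=np.float64)
    sq = np.zeros(C, dtype=np.float64)
    for i in range(M):
        for c in range(C):
            v = x2[i, c]
            s[c] += v
            sq[c] += v * v
    return s, sq


@njit(fastmath=True)
def _nb_pairsums(a, b):
    """Per-column sum(a) and sum(a*b) in one pass: a, b (M, C)."""
    M, C = a.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for i in range(M):
        for c in range(C):
            av = a[i, c]
            s1[c] += av
            s2[c] += av * b[i, c]
    return s1, s2


def _gemm_acc(out: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    """``out += a @ b`` for C-contiguous float32 2-D arrays, without temporaries.

    Computed as ``out.T += b.T @ a.T`` so every operand is Fortran-contiguous
    from BLAS's point of view and the accumulation happens in place.
    """
    if (
        out.dtype == np.float32
        and a.dtype == np.float32
        and b.dtype == np.float32
        and a.flags.c_contiguous
        and b.flags.c_contiguous
        and out.flags.c_contiguous
    ):
        sgemm(1.0, b.T, a.T, beta=1.0, c=out.T, overwrite_c=True)
    else:  # pragma: no cover - fallback for odd dtypes/layouts
        out += a @ b


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def _he(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray, need_param_grads: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-length 1-D convolution on ``(rows, L, C_in)`` channels-last input.

    Two implementations with identical results: a fused single-thread kernel
    for float32 (the training path), and a reference path where rows are laid
    back to back in one flat padded buffer so that every kernel tap becomes a
    single contiguous GEMM over all rows and positions at once (positions
    that would read across a row boundary land in the padded tail and are
    sliced away).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.p = c_in, c_out, kernel, padding
        # W[t] is the (C_in, C_out) weight slice of kernel tap t.
        self.W = Param(_he(rng, (kernel, c_in, c_out), kernel * c_in))
        self.b = Param(np.zeros(c_out))
        self._xbig: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if HAVE_NUMBA and x.dtype == np.float32:
            self._x = np.ascontiguousarray(x)
            self._xbig = None
            if self.c_out == 4:
                return _nb_conv1d_fwd_o4(self._x, self.W.value, self.b.value, self.p)
            return _nb_conv1d_fwd(self._x, self.W.value, self.b.value, self.p)
        return self._forward_ref(x)

    def backward(self, g, need_param_grads=True):
        if self._x is not None:
            g = np.ascontiguousarray(g)
            if self.c_in == 4:
                gx = _nb_conv1d_bwd_gx_c4(self.W.value, g, self.p, self._x.shape[1])
                if need_param_grads:
                    gW, gb = _nb_conv1d_bwd_params(self._x, g, self.p, self.k)
                    self.W.grad += gW
                    self.b.grad += gb
                return gx
            gx, gW, gb = _nb_conv1d_bwd(self._x, self.W.value, g, self.p, need_param_grads)
            if need_param_grads:
                self.W.grad += gW
                self.b.grad += gb
            return gx
        return self._backward_ref(g, need_param_grads)

    def _forward_ref(self, x, train=False):
        self._x = None
        rows, length, _ = x.shape
        lp = length + 2 * self.p
        m = rows * lp
        xbig = np.zeros((m + self.k, self.c_in), dtype=F32)
        xbig[:m].reshape(rows, lp, self.c_in)[:, self.p : self.p + length, :] = x
        self._xbig, self._dims = xbig, (rows, length, lp)

        ybig = np.empty((m, self.c_out), dtype=F32)
        ybig[:] = self.b.value
        for t in range(self.k):
            _gemm_acc(ybig, xbig[t : t + m], self.W.value[t])
        # valid output positions are l in [0, L) of each padded row
        return ybig.reshape(rows, lp, self.c_out)[:, :length, :]

    def _backward_ref(self, g, need_param_grads=True):
        rows, length, lp = self._dims
        m = rows * lp
        gpad = np.zeros((m, self.c_out), dtype=F32)
        gpad.reshape(rows, lp, self.c_out)[:, :length, :] = g
        if need_param_grads:
            for t in range(self.k):
                self.W.grad[t] += self._xbig[t : t + m].T @ gpad
            self.b.grad += g.reshape(-1, self.c_out).sum(axis=0)
        gxbig = np.zeros((m + self.k, self.c_in), dtype=F32)
        wt = np.ascontiguousarray(self.W.value.transpose(0, 2, 1))  # (k, C_out, C_in)
        for t in range(self.k):
            _gemm_acc(gxbig[t : t + m], gpad, wt[t])
        return np.ascontiguousarray(
            gxbig[:m].reshape(rows, lp, self.c_in)[:, self.p : self.p + length, :]
        )


class Conv2d(Layer):
    """Same-size k x k convolution on ``(N, H, W, C_in)`` channels-last input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.p = c_in, c_out, kernel, padding
        self.W = Param(_he(rng, (kernel * kernel * c_in, c_out), kernel * kernel * c_in))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _cols(self, xp: np.ndarray) -> np.ndarray:
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # (N, H, W, C, k, k)
        return win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, self.k * self.k * self.c_in)

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.p, self.p), (self.p, self.p), (0, 0)))
        self._xp, self._hw = xp, (h, w)
        y = self._cols(xp) @ self.W.value + self.b.value
        return y.reshape(n, h, w, self.c_out)

    def backward(self, g, need_param_grads=True):
        n, h, w, _ = g.shape
        g2 = g.reshape(-1, self.c_out)
        if need_param_grads:
            cols = self._cols(self._xp)
            self.W.grad += cols.T @ g2
            self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.T).reshape(n, h, w, self.k, self.k, self.c_in)
        gxp = np.zeros_like(self._xp)
        for u in range(self.k):
            for v in range(self.k):
                gxp[:, u : u + h, v : v + w, :] += gcols[:, :, :, u, v, :]
        return gxp[:, self.p : self.p + h, self.p : self.p + w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        self._mask = y > 0
        return y

    def backward(self, g, need_param_grads=True):
        return g * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes except the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        c = x.shape[-1]
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        if train:
            if HAVE_NUMBA and x2.dtype == np.float32:
                s, sq = _nb_colsums(x2)
                mean64 = s / len(x2)
                mean = mean64.astype(F32)
                var = (sq / len(x2) - mean64**2).astype(F32)
            else:
                mean = x2.mean(axis=0, dtype=np.float64).astype(F32)
                var = (
                    np.einsum("ij,ij->j", x2, x2, dtype=np.float64) / len(x2)
                    - mean.astype(np.float64) ** 2
                ).astype(F32)
            np.clip(var, 0, None, out=var)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._inv_std, self._train = inv_std, train
        if not train:
            # fused scale-and-shift; xhat is reconstructed lazily if a
            # backward pass (saliency) needs it
            self._x2, self._mean, self._xhat = x2, mean, None
            y = x2 * (self.gamma.value * inv_std)
            y += self.beta.value - mean * self.gamma.value * inv_std
            return y.reshape(x.shape)
        if HAVE_NUMBA and x2.dtype == np.float32:
            xhat, y = _nb_bn_fwd_train(x2, mean, inv_std, self.gamma.value, self.beta.value)
            self._xhat = xhat
            return y.reshape(x.shape)
        xhat = (x2 - mean) * inv_std
        self._xhat = xhat
        y = xhat * self.gamma.value
        y += self.beta.value
        return y.reshape(x.shape)

    def backward(self, g, need_param_grads=True):
        shape = g.shape
        g2 = np.ascontiguousarray(g).reshape(-1, shape[-1])
        if self._xhat is None:  # eval-mode forward skipped the xhat cache
            self._xhat = (self._x2 - self._mean) * self._inv_std
        if HAVE_NUMBA and g2.dtype == np.float32 and self._xhat.dtype == np.float32:
            s1, s2 = _nb_pairsums(g2, self._xhat)
        else:
            s1 = g2.sum(axis=0, dtype=np.float64)
            s2 = np.einsum("ij,ij->j", g2, self._xhat, dtype=np.float64)
        if need_param_grads:
            self.gamma.grad += s2
            self.beta.grad += s1
        if not self._train:
            gg = g2 * (self.gamma.value * self._inv_std)
            return gg.reshape(shape)
        m = len(g2)
        m1 = (self.gamma.value * s1 / m).astype(g2.dtype)
        m2 = (self.gamma.value * s2 / m).astype(g2.dtype)
        if HAVE_NUMBA and g2.dtype == np.float32:
            gx = _nb_bn_bwd_train(
                g2, self._xhat, self.gamma.value, self._inv_std, m1, m2
            )
            return gx.reshape(shape)
        gg = g2 * self.gamma.value
        gg -= m1
        gg -= self._xhat * m2
        gg *= self._inv_std
        return gg.reshape(shape)


class MaxPool2d(Layer):
    """2 x 2, stride-2 max pooling on ``(N, H, W, C)`` (even H, W required)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {(h, w)}")
        win = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        self._idx = np.argmax(win, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g, need_param_grads=True):
        n, h, w, c = self._shape
        gwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(gwin, self._idx[..., None], g[..., None], axis=-1)
        return (
            gwin.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


def _adaptive_bins(length: int, out: int) -> list[tuple[int, int]]:
    return [((i * length) // out, -((-(i + 1) * length) // out)) for i in range(out)]


class AdaptiveAvgPool1d(Layer):
    """Average pooling of ``(rows, L, C)`` to a fixed output length."""

    def __init__(self, out_len: int):
        self.out_len = out_len

    def forward(self, x, train=False):
        rows, length, c = x.shape
        self._length = length
        self._bins = _adaptive_bins(length, self.out_len)
        # exact for any (possibly overlapping) floor/ceil bins: one cumsum
        # pass plus a cheap gather, instead of one slice-mean per bin
        prefix = np.zeros((rows, length + 1, c), dtype=x.dtype)
        np.cumsum(x, axis=1, out=prefix[:, 1:, :])
        starts = np.array([s for s, _ in self._bins])
        ends = np.array([e for _, e in self._bins])
        sizes = (ends - starts).astype(x.dtype)
        return (prefix[:, ends, :] - prefix[:, starts, :]) / sizes[None, :, None]

    def backward(self, g, need_param_grads=True):
        rows, _, c = g.shape
        gx = np.zeros((rows, self._length, c), dtype=g.dtype)
        for i, (s, e) in enumerate(self._bins):
            gx[:, s:e, :] += g[:, i : i + 1, :] / (e - s)
        return gx


class AdaptiveAvgPool2d(Layer):
    """Average pooling of ``(N, H, W, C)`` to a fixed (out x out) grid."""

    def __init__(self, out: int):
        self.out = out

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._shape = x.shape
        self._rbins = _adaptive_bins(h, self.out)
        self._cbins = _adaptive_bins(w, self.out)
        y = np.empty((n, self.out, self.out, c), dtype=x.dtype)
        for i, (rs, re) in enumerate(self._rbins):
            for j, (cs, ce) in enumerate(self._cbins):
                y[:, i, j, :] = x[:, rs:re, cs:ce, :].mean(axis=(1, 2))
        return y

    def backward(self, g, need_param_grads=True):
        gx = np.zeros(self._shape, dtype=g.dtype)
        for i, (rs, re) in enumerate(self._rbins):
            for j, (cs, ce) in enumerate(self._cbins):
                gx[:, rs:re, cs:ce, :] += g[:, i : i + 1, j : j + 1, :] / (
                    (re - rs) * (ce - cs)
                )
        return gx


class MeanOverAxis1(Layer):
    """Mean over axis 1: ``(rows, P, C) -> (rows, C)``."""

    def forward(self, x, train=False):
        self._p = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g, need_param_grads=True):
        scaled = g / self._p
        return np.broadcast_to(scaled[:, None, :], (g.shape[0], self._p, g.shape[1]))


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_he(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g, need_param_grads=True):
        if need_param_grads:
            self.W.grad += self._x.T @ g
            self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, g, need_param_grads=True):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g, need_param_grads=True):
        return g.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g, need_param_grads=True):
        for layer in reversed(self.layers):
            g = layer.backward(g, need_param_grads)
        return g


class Adam:
    """Adam with (classic) L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most ``max_norm``."""
        total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.params))
        if total > max_norm > 0:
            scale = F32(max_norm / total)
            for p in self.params:
                p.grad *= scale
        return total

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


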