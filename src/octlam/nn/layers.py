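"""Numpy layers for 3D convolutional networks, with hand-written backprop.

Convolution is im2col + BLAS matmul; the input-gradient scatter (col2im)
is a ``bincount`` over a precomputed flat index map, cached per input
shape.  All arrays are float64, NCDHW layout.
"""

from __future__ import annotations

import numpy as np

from .core import Module


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _windows(xp: np.ndarray, k: tuple[int, int, int], s: tuple[int, int, int]) -> np.ndarray:
    """Strided sliding windows of a padded (N,C,Dp,Hp,Wp) array.

    Returns a view of shape (N, C, Do, Ho, Wo, kd, kh, kw).
    """
    v = np.lib.stride_tricks.sliding_window_view(xp, k, axis=(2, 3, 4))
    return v[:, :, :: s[0], :: s[1], :: s[2]]


def conv_output_shape(spatial, k, s, p):
    return tuple((n + 2 * pi - ki) // si + 1 for n, ki, si, pi in zip(spatial, k, s, p))


class Conv3d(Module):
    """3D convolution, optional bias, Kaiming fan-out init."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        self.cin, self.cout = int(cin), int(cout)
        self.k = _triple(kernel)
        self.s = _triple(stride)
        self.p = _triple(padding)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_out = self.cout * int(np.prod(self.k))
        std = np.sqrt(2.0 / fan_out)
        self.weight = self.add_param(
            rng.normal(0.0, std, size=(self.cout, self.cin, *self.k)), "conv.weight"
        )
        self.bias = self.add_param(np.zeros(self.cout), "conv.bias") if bias else None
        self._idx_cache: tuple | None = None  # (xshape, flat index map)

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        pd, ph, pw = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        v = _windows(xp, self.k, self.s)  # (N,C,Do,Ho,Wo,kd,kh,kw)
        do, ho, wo = v.shape[2:5]
        kvol = int(np.prod(self.k))
        cols = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * kvol)
        wmat = self.weight.data.reshape(self.cout, c * kvol)
        out = cols @ wmat.T  # (N, L, Cout)
        if self.bias is not None:
            out += self.bias.data
        self._cache = (x.shape, xp.shape, cols, (do, ho, wo))
        return out.transpose(0, 2, 1).reshape(n, self.cout, do, ho, wo)

    def _flat_index(self, xpshape, outsp):
        """Map (position l, col element kk) -> flat index into padded (C,Dp,Hp,Wp)."""
        key = (xpshape, outsp)
        if self._idx_cache is not None and self._idx_cache[0] == key:
            return self._idx_cache[1]
        _, cch, dp, hp, wp = xpshape
        do, ho, wo = outsp
        kd, kh, kw = self.k
        sd, sh, sw = self.s
        zo = (np.arange(do) * sd)[:, None, None]
        yo = (np.arange(ho) * sh)[None, :, None]
        xo = (np.arange(wo) * sw)[None, None, :]
        kz = np.arange(kd)[:, None, None]
        ky = np.arange(kh)[None, :, None]
        kx = np.arange(kw)[None, None, :]
        # spatial flat index for each (l, kernel offset)
        sp = (
            (zo[..., None, None, None] + kz) * (hp * wp)
            + (yo[..., None, None, None] + ky) * wp
            + (xo[..., None, None, None] + kx)
        ).reshape(do * ho * wo, kd * kh * kw)
        coff = np.arange(cch) * (dp * hp * wp)
        idx = (coff[None, :, None] + sp[:, None, :]).reshape(
            do * ho * wo, cch * kd * kh * kw
        )
        self._idx_cache = (key, idx)
        return idx

    def backward(self, dout):
        xshape, xpshape, cols, outsp = self._cache
        n = xshape[0]
        do, ho, wo = outsp
        dmat = dout.reshape(n, self.cout, do * ho * wo).transpose(0, 2, 1)  # (N,L,Cout)
        wmat = self.weight.data.reshape(self.cout, -1)
        dw = np.einsum("nlo,nlk->ok", dmat, cols)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=(0, 1))
        dcols = dmat @ wmat  # (N, L, C*kvol)
        idx = self._flat_index(xpshape, outsp)
        size = int(np.prod(xpshape[1:]))
        dxp = np.empty(xpshape)
        flat = idx.ravel()
        for i in range(n):
            dxp[i] = np.bincount(flat, weights=dcols[i].ravel(), minlength=size).reshape(
                xpshape[1:]
            )
        pd, ph, pw = self.p
        _, _, d, h, w = xshape
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class BatchNorm3d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c = int(channels)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = self.add_param(np.ones(self.c), "bn.gamma")
        self.beta = self.add_param(np.zeros(self.c), "bn.beta")
        self.running_mean = self.add_buffer(np.zeros(self.c))
        self.running_var = self.add_buffer(np.ones(self.c))

    def forward(self, x, train=False):
        if train:
            axes = (0, 2, 3, 4)
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        sh = (1, self.c, 1, 1, 1)
        xhat = (x - mu.reshape(sh)) * invstd.reshape(sh)
        self._cache = (xhat, invstd, train, x.shape)
        return self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)

    def backward(self, dout):
        xhat, invstd, train, xshape = self._cache
        sh = (1, self.c, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data.reshape(sh)
        if not train:
            return dxhat * invstd.reshape(sh)
        m = xshape[0] * xshape[2] * xshape[3] * xshape[4]
        # standard batch-norm backward through the batch statistics
        t = dxhat - dxhat.mean(axis=axes).reshape(sh) - xhat * (dxhat * xhat).mean(
            axis=axes
        ).reshape(sh)
        return t * invstd.reshape(sh)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.k = _triple(kernel)
        self.s = _triple(stride)
        self.p = _triple(padding)

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        pd, ph, pw = self.p
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
            constant_values=-np.inf,
        )
        v = _windows(xp, self.k, self.s)
        do, ho, wo = v.shape[2:5]
        kvol = int(np.prod(self.k))
        vflat = v.reshape(n, c, do * ho * wo, kvol)
        arg = vflat.argmax(axis=3)
        out = np.take_along_axis(vflat, arg[..., None], axis=3)[..., 0]
        self._cache = (x.shape, xp.shape, (do, ho, wo), arg)
        return out.reshape(n, c, do, ho, wo)

    def backward(self, dout):
        xshape, xpshape, outsp, arg = self._cache
        n, c = xshape[:2]
        do, ho, wo = outsp
        dp, hp, wp = xpshape[2:]
        kd, kh, kw = self.k
        sd, sh, sw = self.s
        l = do * ho * wo
        # flat spatial index of each window element, per position
        zo = (np.arange(do) * sd)[:, None, None]
        yo = (np.arange(ho) * sh)[None, :, None]
        xo = (np.arange(wo) * sw)[None, None, :]
        kz = np.arange(kd)[:, None, None]
        ky = np.arange(kh)[None, :, None]
        kx = np.arange(kw)[None, None, :]
        sp = (
            (zo[..., None, None, None] + kz) * (hp * wp)
            + (yo[..., None, None, None] + ky) * wp
            + (xo[..., None, None, None] + kx)
        ).reshape(l, kd * kh * kw)
        chosen = np.take_along_axis(
            sp[None, None, :, :], arg[..., None], axis=3
        )[..., 0]  # (N,C,L) spatial flat index
        psp = dp * hp * wp
        base = (np.arange(n * c) * psp).reshape(n, c, 1)
        flat = (chosen + base).ravel()
        dxp = np.bincount(flat, weights=dout.reshape(n, c, l).ravel(), minlength=n * c * psp)
        dxp = dxp.reshape(n, c, dp, hp, wp)
        pd_, ph_, pw_ = self.p
        _, _, d, h, w = xshape
        return dxp[:, :, pd_ : pd_ + d, ph_ : ph_ + h, pw_ : pw_ + w]


class GlobalAvgPool3d(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, d, h, w = self._shape
        g = dout.reshape(n, c, 1, 1, 1) / float(d * h * w)
        return np.broadcast_to(g, self._shape).copy()


class Linear(Module):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = 1.0 / np.sqrt(cin)
        self.weight = self.add_param(
            rng.uniform(-bound, bound, size=(cout, cin)), "linear.weight"
        )
        self.bias = self.add_param(np.zeros(cout), "linear.bias")

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data
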