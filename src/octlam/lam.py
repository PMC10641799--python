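"""Lesion-aware attention: mask-guided self-attention in the residual CNN.

At an insertion site with features X (C channels, N = D*H*W positions), the
binary lesion mask is resampled to the site's grid and multiplied into X to
give the lesion-related feature X_L.  Two channel-preserving 1x1x1
convolutions produce X_LC (from X_L; used as both query and key) and X_C
(from X; the value).  The module output is

    A_L = rowwise_softmax(X_LC^T X_LC) X_C + X_C

reshaped back to the site's grid, so it can replace X in the backbone.
The residual is added in the value-projected space, exactly as the update
rule is stated; an optional "literal" bracketing variant applies the
rowwise softmax only after multiplying by the value matrix.  No 1/sqrt(d)
attention scaling is applied by default (an optional flag turns it on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import BackboneConfig, ResNet3D
from .nn import Module
from .nn.loss import softmax


@dataclass(frozen=True)
class LamConfig:
    insertion: str = "per_stage"  # "per_stage" | "per_block"
    mask_resample: str = "nearest"  # "nearest" | "trilinear"
    bracketing: str = "standard"  # "standard" | "literal"
    scaled: bool = False  # 1/sqrt(C) attention scaling

    def __post_init__(self):
        if self.insertion not in ("per_stage", "per_block"):
            raise ValueError(f"unknown insertion {self.insertion!r}")
        if self.mask_resample not in ("nearest", "trilinear"):
            raise ValueError(f"unknown mask_resample {self.mask_resample!r}")
        if self.bracketing not in ("standard", "literal"):
            raise ValueError(f"unknown bracketing {self.bracketing!r}")


def resample_mask(mask: np.ndarray, shape: tuple[int, int, int], method: str = "nearest") -> np.ndarray:
    """Resample a (..., D, H, W) mask to spatial ``shape``; nearest stays binary."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape[-3:] == tuple(shape):
        return mask
    if method == "nearest":
        idx = [
            np.minimum((np.arange(t) + 0.5) * s / t, s - 1).astype(np.intp)
            for t, s in zip(shape, mask.shape[-3:])
        ]
        return mask[..., idx[0][:, None, None], idx[1][None, :, None], idx[2][None, None, :]]
    from skimage.transform import resize

    out_shape = mask.shape[:-3] + tuple(shape)
    from skimage.transform import resize as _resize

    return _resize(mask, out_shape, order=1, preserve_range=True, anti_aliasing=False)


class LesionAttention(Module):
    """Mask-guided self-attention over all spatial positions of a feature map."""

    def __init__(self, channels: int, rng=None, bracketing: str = "standard", scaled: bool = False):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = int(channels)
        self.channels = c
        self.bracketing = bracketing
        self.scaled = scaled
        bound = 1.0 / np.sqrt(c)
        self.wq = self.add_param(rng.uniform(-bound, bound, size=(c, c)), "lam.wq")
        self.bq = self.add_param(np.zeros(c), "lam.bq")
        self.wv = self.add_param(rng.uniform(-bound, bound, size=(c, c)), "lam.wv")
        self.bv = self.add_param(np.zeros(c), "lam.bv")
        self._mask: np.ndarray | None = None

    def set_mask(self, mask: np.ndarray) -> None:
        """Mask on this site's (D, H, W) grid, or batched (N, D, H, W)."""
        mask = np.asarray(mask, dtype=np.float64)
        if mask.ndim == 3:
            mask = mask[None]
        self._mask = mask

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if self._mask is None or self._mask.shape[1:] != (d, h, w):
            raise ValueError(f"mask missing or mis-shaped for feature grid {(d, h, w)}")
        if self._mask.shape[0] not in (1, n):
            raise ValueError("mask batch size must be 1 or match the input batch")
        p = d * h * w
        xf = x.reshape(n, c, p)
        xb = self._mask.reshape(self._mask.shape[0], 1, p)
        xl = xf * xb
        m = np.einsum("qc,ncp->nqp", self.wq.data, xl) + self.bq.data[None, :, None]
        v = np.einsum("qc,ncp->nqp", self.wv.data, xf) + self.bv.data[None, :, None]
        scale = 1.0 / np.sqrt(c) if self.scaled else 1.0
        s = np.einsum("ncp,ncq->npq", m, m) * scale  # (N, P, P)
        if self.bracketing == "standard":
            a = softmax(s, axis=2)
            out = np.einsum("ncq,npq->ncp", v, a) + v
            self._cache = (x.shape, xf, xb, xl, m, v, a, scale, None)
        else:  # literal: softmax after applying the value matrix
            zmat = np.einsum("npq,ncq->npc", s, v)  # (N, P, C)
            a = softmax(zmat, axis=2)
            out = a.transpose(0, 2, 1) + v
            self._cache = (x.shape, xf, xb, xl, m, v, a, scale, s)
        return out.reshape(n, c, d, h, w)

    def backward(self, dout):
        xshape, xf, xb, xl, m, v, a, scale, s = self._cache
        n, c = xshape[:2]
        p = xf.shape[2]
        dy = dout.reshape(n, c, p)
        if self.bracketing == "standard":
            dv = np.einsum("ncp,npq->ncq", dy, a) + dy
            da = np.einsum("ncp,ncq->npq", dy, v)
            ds = a * (da - (da * a).sum(axis=2, keepdims=True))
        else:
            da = dy.transpose(0, 2, 1)  # (N, P, C)
            dz = a * (da - (da * a).sum(axis=2, keepdims=True))
            ds = np.einsum("npc,ncq->npq", dz, v)
            dv = np.einsum("npq,npc->ncq", s, dz) + dy
        ds = ds * scale
        dm = np.einsum("ncq,npq->ncp", m, ds) + np.einsum("ncp,npq->ncq", m, ds)
        self.wq.grad += np.einsum("nqp,ncp->qc", dm, xl)
        self.bq.grad += dm.sum(axis=(0, 2))
        self.wv.grad += np.einsum("nqp,ncp->qc", dv, xf)
        self.bv.grad += dv.sum(axis=(0, 2))
        dxl = np.einsum("qc,nqp->ncp", self.wq.data, dm)
        dxf = np.einsum("qc,nqp->ncp", self.wv.data, dv) + dxl * xb
        return dxf.reshape(xshape)


def lam_forward(
    x: np.ndarray, mask: np.ndarray, module: LesionAttention, train: bool = False
) -> np.ndarray:
    """Functional wrapper: resample the mask to x's grid and attend."""
    mask = np.asarray(mask)
    if mask.ndim not in (3, 4):
        raise ValueError("mask must be (D, H, W) or (N, D, H, W)")
    module.set_mask(resample_mask(mask, x.shape[2:], "nearest"))
    return module.forward(x, train)


class LamNetwork(Module):
    """Backbone with a lesion-aware attention module at each insertion site.

    Forward takes the (N, 1, D, H, W) volume input and a mask at volume
    resolution, (D, H, W) or batched (N, D, H, W); the mask is resampled
    to each site's grid.
    """

    def __init__(self, backbone_cfg: BackboneConfig, lam_cfg: LamConfig = LamConfig(), rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.lam_cfg = lam_cfg
        self.backbone = self.add_child(ResNet3D(backbone_cfg, rng=rng))
        self.lams: list[list[LesionAttention]] = []
        for stage, ch in zip(self.backbone.stages, self.backbone.stage_channels()):
            count = 1 if lam_cfg.insertion == "per_stage" else len(stage.modules)
            mods = [
                LesionAttention(ch, rng, lam_cfg.bracketing, lam_cfg.scaled)
                for _ in range(count)
            ]
            for mod in mods:
                self.add_child(mod)
            self.lams.append(mods)

    def n_attention_modules(self) -> int:
        return sum(len(ms) for ms in self.lams)

    def lam_parameters(self):
        return [p for ms in self.lams for m in ms for p in m.parameters()]

    def forward(self, x, mask=None, train=False):
        if mask is None:
            raise ValueError("LamNetwork.forward requires a lesion mask")
        mask = np.asarray(mask, dtype=np.float64)
        if mask.ndim == 3:
            mask = mask[None]
        if mask.shape[0] not in (1, x.shape[0]):
            raise ValueError("mask batch size must be 1 or match the input batch")
        bb = self.backbone
        h = bb.stem.forward(x, train)
        for stage, mods in zip(bb.stages, self.lams):
            if self.lam_cfg.insertion == "per_stage":
                h = stage.forward(h, train)
                h = self._attend(mods[0], h, mask, train)
            else:
                for block, mod in zip(stage.modules, mods):
                    h = block.forward(h, train)
                    h = self._attend(mod, h, mask, train)
        z = bb.gap.forward(h, train)
        return bb.fc.forward(z, train)

    def _attend(self, mod: LesionAttention, h, mask, train):
        mod.set_mask(resample_mask(mask, h.shape[2:], self.lam_cfg.mask_resample))
        return mod.forward(h, train)

    def backward(self, dlogits):
        bb = self.backbone
        g = bb.gap.backward(bb.fc.backward(dlogits))
        for stage, mods in zip(reversed(bb.stages), reversed(self.lams)):
            if self.lam_cfg.insertion == "per_stage":
                g = mods[0].backward(g)
                g = stage.backward(g)
            else:
                for block, mod in zip(reversed(stage.modules), reversed(mods)):
                    g = mod.backward(g)
                    g = block.backward(g)
        return bb.stem.backward(g)


def build_lam_network(
    backbone_cfg: BackboneConfig, lam_cfg: LamConfig = LamConfig(), rng=None
) -> LamNetwork:
    return LamNetwork(backbone_cfg, lam_cfg, rng=rng)
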