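"""3D residual CNN backbone (depths 18/34/50/101) for OCT volume classification.

The network is the standard 3D-ResNet recipe: a 7x7x7 stride-2 stem with
max-pooling, four residual stages (basic blocks for depths 18/34,
bottlenecks for 50/101), global average pooling and a linear head.  The
depth axis is strided like H and W by default; volumes of 70 slices
tolerate the four halvings.  Stage outputs are exposed as named taps so
Grad-CAM can differentiate class scores w.r.t. them, and gradients at the
taps are captured during the backward pass.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool3d,
    Linear,
    MaxPool3d,
    Module,
    ReLU,
    Sequential,
)

_BLOCKS_PER_STAGE = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3), 50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}
STAGE_NAMES = ("stage1", "stage2", "stage3", "stage4")


@dataclass(frozen=True)
class BackboneConfig:
    depth: int = 18
    n_classes: int = 2
    base_channels: int = 64
    stage_taps: tuple[str, ...] = STAGE_NAMES
    downsample_depth: bool = True

    def __post_init__(self):
        if self.depth not in _BLOCKS_PER_STAGE:
            raise ValueError(f"unsupported depth {self.depth}; choose from 18/34/50/101")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for t in self.stage_taps:
            if t not in STAGE_NAMES:
                raise ValueError(f"unknown tap {t!r}")


class BasicBlock(Module):
    expansion = 1

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = self.add_child(Conv3d(cin, cout, 3, stride, 1, bias=False, rng=rng))
        self.bn1 = self.add_child(BatchNorm3d(cout))
        self.relu1 = self.add_child(ReLU())
        self.conv2 = self.add_child(Conv3d(cout, cout, 3, 1, 1, bias=False, rng=rng))
        self.bn2 = self.add_child(BatchNorm3d(cout))
        self.relu2 = self.add_child(ReLU())
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = self.add_child(
                Sequential(Conv3d(cin, cout, 1, stride, 0, bias=False, rng=rng), BatchNorm3d(cout))
            )

    def forward(self, x, train=False):
        idn = x if self.downsample is None else self.downsample.forward(x, train)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        return self.relu2.forward(h + idn, train)

    def backward(self, dout):
        g = self.relu2.backward(dout)
        gid = g
        gm = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.bn2.backward(self.conv2.backward(g))))
        )
        if self.downsample is not None:
            gid = self.downsample.backward(gid)
        return gm + gid


class Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        cexp = cout * self.expansion
        self.conv1 = self.add_child(Conv3d(cin, cout, 1, 1, 0, bias=False, rng=rng))
        self.bn1 = self.add_child(BatchNorm3d(cout))
        self.relu1 = self.add_child(ReLU())
        self.conv2 = self.add_child(Conv3d(cout, cout, 3, stride, 1, bias=False, rng=rng))
        self.bn2 = self.add_child(BatchNorm3d(cout))
        self.relu2 = self.add_child(ReLU())
        self.conv3 = self.add_child(Conv3d(cout, cexp, 1, 1, 0, bias=False, rng=rng))
        self.bn3 = self.add_child(BatchNorm3d(cexp))
        self.relu3 = self.add_child(ReLU())
        self.downsample = None
        if stride != 1 or cin != cexp:
            self.downsample = self.add_child(
                Sequential(Conv3d(cin, cexp, 1, stride, 0, bias=False, rng=rng), BatchNorm3d(cexp))
            )

    def forward(self, x, train=False):
        idn = x if self.downsample is None else self.downsample.forward(x, train)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)
        h = self.bn3.forward(self.conv3.forward(h, train), train)
        return self.relu3.forward(h + idn, train)

    def backward(self, dout):
        g = self.relu3.backward(dout)
        gid = g
        gm = self.bn3.backward(self.conv3.backward(g))
        gm = self.bn2.backward(self.conv2.backward(self.relu2.backward(gm)))
        gm = self.bn1.backward(self.conv1.backward(self.relu1.backward(gm)))
        gm = gm  # conv1 path complete
        if self.downsample is not None:
            gid = self.downsample.backward(gid)
        return gm + gid


class ResNet3D(Module):
    """3D ResNet emitting class scores; stage outputs available as taps."""

    def __init__(self, cfg: BackboneConfig, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        block_cls = BasicBlock if cfg.depth in (18, 34) else Bottleneck
        self.block_cls = block_cls
        b = cfg.base_channels
        self.stem = self.add_child(
            Sequential(
                Conv3d(1, b, 7, 2, 3, bias=False, rng=rng),
                BatchNorm3d(b),
                ReLU(),
                MaxPool3d(3, 2, 1),
            )
        )
        widths = (b, 2 * b, 4 * b, 8 * b)
        strides = (1, 2, 2, 2)
        self.stages: list[Sequential] = []
        cin = b
        for w, s, nblocks in zip(widths, strides, _BLOCKS_PER_STAGE[cfg.depth]):
            sdepth = s if cfg.downsample_depth else 1
            blocks = []
            for i in range(nblocks):
                st = (sdepth, s, s) if i == 0 else 1
                blocks.append(block_cls(cin, w, st, rng))
                cin = w * block_cls.expansion
            stage = self.add_child(Sequential(*blocks))
            self.stages.append(stage)
        self.gap = self.add_child(GlobalAvgPool3d())
        self.fc = self.add_child(Linear(cin, cfg.n_classes, rng=rng))
        self.feature_channels = cin
        self._feats: dict[str, np.ndarray] = {}
        self.tap_grads: dict[str, np.ndarray] = {}

    def stage_channels(self) -> tuple[int, ...]:
        b = self.cfg.base_channels
        e = self.block_cls.expansion
        return tuple(b * m * e for m in (1, 2, 4, 8))

    def forward(self, x, train=False):
        h = self.stem.forward(x, train)
        self._feats = {}
        for name, stage in zip(STAGE_NAMES, self.stages):
            h = stage.forward(h, train)
            if name in self.cfg.stage_taps:
                self._feats[name] = h
        z = self.gap.forward(h, train)
        return self.fc.forward(z, train)

    def backward(self, dlogits, capture: set[str] | None = None):
        capture = capture or set()
        unknown = capture - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown taps {sorted(unknown)}")
        self.tap_grads = {}
        g = self.gap.backward(self.fc.backward(dlogits))
        for name, stage in zip(reversed(STAGE_NAMES), reversed(self.stages)):
            if name in capture:
                self.tap_grads[name] = g
            g = stage.backward(g)
        return self.stem.backward(g)

    def features(self) -> dict[str, np.ndarray]:
        return self._feats


def build_backbone(cfg: BackboneConfig, rng=None) -> ResNet3D:
    return ResNet3D(cfg, rng=rng)


def forward_with_features(model: ResNet3D, volume) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Class scores plus the activations at each configured tap.

    ``volume`` is a :class:`octlam.preprocess.Volume` or a raw (H, W, D) array.
    """
    x = volume_to_input(volume)
    scores = model.forward(x, train=False)[0]
    feats = {k: v[0] for k, v in model.features().items()}
    return scores, feats


def volume_to_input(volume) -> np.ndarray:
    """(H, W, D) volume data -> network input of shape (1, 1, D, H, W)."""
    data = getattr(volume, "data", volume)
    x = np.moveaxis(np.asarray(data, dtype=np.float64), -1, 0)
    return x[None, None]


def save_checkpoint(model: Module, path, config: dict | None = None) -> None:
    arrays = {f"arr_{i:05d}": a for i, a in enumerate(model.state_arrays())}
    meta = json.dumps(config or {}, sort_keys=True)
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[list[np.ndarray], dict]:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode()) if "__config__" in z else {}
        keys = sorted(k for k in z.files if k.startswith("arr_"))
        arrays = [z[k] for k in keys]
    return arrays, cfg


def backbone_config_dict(cfg: BackboneConfig) -> dict:
    d = asdict(cfg)
    d["stage_taps"] = list(cfg.stage_taps)
    return d


def backbone_config_from_dict(d: dict) -> BackboneConfig:
    d = dict(d)
    if "stage_taps" in d:
        d["stage_taps"] = tuple(d["stage_taps"])
    return BackboneConfig(**d)
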