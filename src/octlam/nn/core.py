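"""Minimal module/parameter machinery for the numpy network layers.

Every layer is a :class:`Module` with an explicit ``forward``/``backward``
pair; gradients are accumulated into :class:`Parameter.grad` by ``backward``.
Construction order of parameters is deterministic, which is what the
checkpoint format and the stage-2 warm start rely on.
"""

from __future__ import annotations

import hashlib

import numpy as np


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.data.shape})"


class Module:
    """Base class: tracks parameters, buffers and child modules."""

    def __init__(self) -> None:
        self._params: list[Parameter] = []
        self._buffers: list[np.ndarray] = []
        self._children: list["Module"] = []

    def add_param(self, data: np.ndarray, name: str = "") -> Parameter:
        p = Parameter(data, name)
        self._params.append(p)
        return p

    def add_buffer(self, data: np.ndarray) -> np.ndarray:
        b = np.asarray(data, dtype=np.float64)
        self._buffers.append(b)
        return b

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def buffers(self) -> list[np.ndarray]:
        out = list(self._buffers)
        for c in self._children:
            out.extend(c.buffers())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters then buffers, in deterministic construction order."""
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError(
                f"state mismatch: expected {len(targets)} arrays, got {len(arrays)}"
            )
        for dst, src in zip(targets, arrays):
            if dst.shape != np.shape(src):
                raise ValueError(f"shape mismatch: {dst.shape} vs {np.shape(src)}")
            dst[...] = src

    def checksum(self) -> str:
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.modules = list(modules)
        for m in self.modules:
            self.add_child(m)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout
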