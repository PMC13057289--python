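"""Module base class: parameter registration, mode flags, state dicts."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------
    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Tensor]:
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in self._buffers:
            yield prefix + n, self._buffers[n]
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation --------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            d["buffer:" + n] = np.array(b, copy=True)
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for n, p in params.items():
            if n not in d:
                raise KeyError(f"missing parameter {n!r} in state dict")
            arr = np.asarray(d[n])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n!r}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)
            p.grad = None
        for n, _ in self.named_buffers():
            key = "buffer:" + n
            if key in d:
                self._assign_buffer(n, np.asarray(d[key]))

    def _assign_buffer(self, dotted: str, arr: np.ndarray):
        mod: Module = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod._buffers[leaf][...] = arr
        object.__setattr__(mod, leaf, mod._buffers[leaf])

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]
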