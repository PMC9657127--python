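"""Minimal module system: parameters, buffers, and a composable layer tree.

Layers implement ``forward`` (caching what backward needs) and ``backward``
(consuming the cache, accumulating gradients into ``Parameter.grad`` and
returning the gradient with respect to their input). The stack is pure
numpy and CPU-oriented; float32 is the working precision for networks, but
no layer hard-casts, so float64 flows through unchanged (used by the
finite-difference gradient tests).
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = ["Parameter", "Module", "Sequential"]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover
        return f"Parameter(shape={self.data.shape}, dtype={self.data.dtype})"


class Module:
    """Base class for layers and composite networks."""

    def __init__(self):
        self._parameters: "OrderedDict[str, Parameter]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    # -- attribute routing -------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _sync_buffer(self, name: str, value: np.ndarray):
        """Update a registered buffer in place of its registry entry."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield (prefix + name, p)
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield (prefix + name, getattr(self, name))
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def num_parameters(self) -> int:
        """Total number of trainable scalar parameters."""
        return int(sum(p.size for p in self.parameters()))

    # -- mode & gradients --------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = np.zeros_like(p.data)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": np.array(v, copy=True) for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.array(value, copy=True)
            elif kind == "buffer":
                self._set_buffer_by_path(name, np.array(value, copy=True))
            else:  # pragma: no cover
                raise KeyError(f"unrecognised state key {key!r}")

    def _set_buffer_by_path(self, path: str, value: np.ndarray):
        mod = self
        *parents, leaf = path.split(".")
        for part in parents:
            mod = mod._modules[part]
        mod._sync_buffer(leaf, value)

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def append(self, layer: Module):
        self._modules[str(len(self.layers))] = layer
        self.layers.append(layer)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out
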