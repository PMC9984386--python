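"""Lightweight module system on top of the autodiff tensors.

Modules register parameters and sub-modules by attribute assignment, expose
them recursively through :meth:`Module.parameters` / :meth:`state_dict`, and
serialize to flat ``name -> ndarray`` dicts for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "LayerNorm", "xavier_uniform"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform init: U(−a, a) with a = sqrt(6/(fan_in+fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-a, a, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + n: p for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.named_parameters(prefix + mn + "."))
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_parameters()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for n, p in own.items():
            arr = np.asarray(state[n], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(xavier_uniform(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, self.eps)
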