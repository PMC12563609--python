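"""Layer abstractions on top of the autograd engine (He-normal init)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d


class Module:
    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def count_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def state_dict(self) -> dict:
        """Flat name -> array mapping (deterministic traversal order)."""
        out = {}

        def walk(mod, prefix):
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor) and value.requires_grad:
                    out[f"{prefix}{name}"] = value.data
                elif isinstance(value, Module):
                    walk(value, f"{prefix}{name}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]} ...")

        def walk(mod, prefix):
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor) and value.requires_grad:
                    value.data = np.asarray(state[f"{prefix}{name}"], dtype=np.float32)
                elif isinstance(value, Module):
                    walk(value, f"{prefix}{name}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")

        walk(self, "")


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad  # same padding by default
        self.weight = Tensor(
            _he_normal(rng, (cout, cin, k, k), cin * k * k), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.weight = Tensor(
            _he_normal(rng, (cin, cout, k, k), cin * k * k), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_normal(rng, (nin, nout), nin), requires_grad=True)
        self.bias = Tensor(np.zeros(nout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias
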