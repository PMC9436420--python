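"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "InstanceNorm2d",
           "LeakyReLU", "ReLU", "ReflectionPad2d", "Sequential"]


class Module:
    """Base class: children discovered by attribute scan, parameters pooled."""

    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def parameters(self):
        params = []
        for val in vars(self).values():
            if isinstance(val, Tensor) and val.requires_grad:
                params.append(val)
        for _, child in self.named_children():
            params.extend(child.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        """Flat list of parameter arrays, in deterministic traversal order."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 *, rng: np.random.Generator, init_std: float = 0.02,
                 bias: bool = True):
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            rng.normal(0.0, init_std, (out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 output_padding=0, *, rng: np.random.Generator,
                 init_std: float = 0.02, bias: bool = True):
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding
        self.weight = Tensor(
            rng.normal(0.0, init_std, (in_ch, out_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class InstanceNorm2d(Module):
    """Per-sample spatial standardization; no affine weights, no running stats,
    so training- and evaluation-mode forwards are identical."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.instance_norm(self.eps)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class ReflectionPad2d(Module):
    def __init__(self, pad: int):
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return x.pad2d(self.pad, mode="reflect")


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
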