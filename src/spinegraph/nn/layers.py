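"""Layer building blocks on top of the autodiff engine.

Conventions: tensors are (N, C, *spatial); He-normal initialization for
convolutions; instance normalization after every convolution; residual
blocks are conv-norm-relu-conv-norm + skip, then relu.  Decoder stages use
nearest upsampling + convolution with additive skip fusion.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv", "ConvBlock", "ResBlock", "Down", "Up"]


class Module:
    """Minimal parameter container with named sub-modules."""

    def params(self) -> list[tuple[str, Tensor]]:
        out = []
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend((f"{name}.{sub}", t) for sub, t in value.params())
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{sub}", t)
                                   for sub, t in item.params())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out

    def state_dict(self) -> dict:
        return {name: t.data.copy() for name, t in self.params()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.params())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter mismatch: {sorted(missing)}")
        for name, t in params.items():
            if t.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = state[name].astype(t.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for _, t in self.params():
            t.zero_grad()


class Conv(Module):
    """nD convolution with optional bias; kernel k, "same" padding."""

    def __init__(self, nd: int, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k ** nd
        scale = np.sqrt(2.0 / fan_in)
        w = np.zeros((cout, cin) + (k,) * nd) if zero_init else \
            rng.normal(0.0, scale, size=(cout, cin) + (k,) * nd)
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) \
            if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv(x, self.w, self.b, stride=self.stride)


class InstanceNorm(Module):
    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)


class ConvBlock(Module):
    """conv -> instance norm -> relu"""

    def __init__(self, nd, cin, cout, k=3, stride=1, rng=None):
        self.conv = Conv(nd, cin, cout, k=k, stride=stride, rng=rng)
        self.norm = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.norm(self.conv(x)))


class ResBlock(Module):
    """Two 3^nd convolutions with a residual skip."""

    def __init__(self, nd, c, rng=None):
        self.conv1 = Conv(nd, c, c, rng=rng)
        self.norm1 = InstanceNorm(c)
        self.conv2 = Conv(nd, c, c, rng=rng)
        self.norm2 = InstanceNorm(c)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ad.relu(ad.add(h, x))


class Down(Module):
    """Stride-2 convolution halving every spatial dim, doubling channels."""

    def __init__(self, nd, cin, cout, rng=None):
        self.block = ConvBlock(nd, cin, cout, stride=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block(x)


class Up(Module):
    """Nearest upsample x2 -> conv to skip width -> norm -> add skip -> relu."""

    def __init__(self, nd, cin, cout, rng=None):
        self.conv = Conv(nd, cin, cout, rng=rng)
        self.norm = InstanceNorm(cout)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.norm(self.conv(ad.upsample_nearest(x)))
        return ad.relu(ad.add(h, skip))
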