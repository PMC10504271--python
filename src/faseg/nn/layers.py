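"""Layer/module abstractions over the autodiff core.

Modules register parameters (trainable tensors) and buffers (running
statistics) in insertion order, giving a deterministic, flat ``state_dict``
used for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            src = state[name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data[...] = src
        for name, b in self.named_buffers():
            b[...] = state[name]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _param(rng: np.random.Generator, shape, std: float) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    """Same-padded NCHW convolution; fan-out-scaled normal init."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int = 1,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.in_c, self.out_c, self.k, self.stride = in_c, out_c, k, stride
        std = np.sqrt(2.0 / (out_c * k * k))
        self.weight = _param(rng, (out_c, in_c, k, k), std)
        self.bias = Tensor(np.zeros(out_c), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, stride: int = 1,
                 *, rng: np.random.Generator):
        super().__init__()
        self.channels, self.k, self.stride = channels, k, stride
        self.weight = _param(rng, (channels, k, k), np.sqrt(2.0 / (k * k)))

    def forward(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv2d(x, self.weight, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=ad.DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=ad.DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = _param(rng, (in_f, out_f), np.sqrt(2.0 / in_f))
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + ad.reshape(self.bias, (1, self.out_f))


class SqueezeExcite(Module):
    """Channel gate from globally pooled features (reduce -> swish -> expand
    -> sigmoid)."""

    def __init__(self, channels: int, se_ratio: float, *, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, int(round(channels * se_ratio)))
        self.reduce = Linear(channels, hidden, rng=rng)
        self.expand = Linear(hidden, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        pooled = ad.global_avg_pool(x)  # (N, C)
        return ad.sigmoid(self.expand(ad.swish(self.reduce(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * ad.reshape(self.gate(x), (n, c, 1, 1))


class MBConv(Module):
    """Mobile inverted bottleneck: expand (1x1) -> depthwise -> squeeze-and-
    excitation -> project (1x1), with a residual skip when stride is 1 and
    channel count is preserved."""

    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1,
                 expansion_ratio: int = 4, se_ratio: float = 0.25,
                 *, rng: np.random.Generator):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"MBConv stride must be 1 or 2, got {stride}")
        mid = in_c * expansion_ratio
        self.has_skip = stride == 1 and in_c == out_c
        self.expand_conv = Conv2d(in_c, mid, 1, bias=False, rng=rng) \
            if expansion_ratio != 1 else None
        self.expand_bn = BatchNorm2d(mid) if expansion_ratio != 1 else None
        self.dw = DepthwiseConv2d(mid, k, stride, rng=rng)
        self.dw_bn = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, se_ratio, rng=rng)
        self.project_conv = Conv2d(mid, out_c, 1, bias=False, rng=rng)
        self.project_bn = BatchNorm2d(out_c)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.expand_conv is not None:
            h = ad.swish(self.expand_bn(self.expand_conv(h)))
        h = ad.swish(self.dw_bn(self.dw(h)))
        h = self.se(h)
        h = self.project_bn(self.project_conv(h))
        if self.has_skip:
            h = h + x
        return h


class MLP(Module):
    """Fully connected readout with rectifier hidden activations and a
    linear output layer."""

    def __init__(self, in_f: int, hidden: list[int], out_f: int,
                 *, rng: np.random.Generator):
        super().__init__()
        widths = [in_f] + list(hidden) + [out_f]
        self.layers = ModuleList(
            [Linear(a, b, rng=rng) for a, b in zip(widths[:-1], widths[1:])]
        )

    def forward(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < n - 1:
                x = ad.relu(x)
        return x
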