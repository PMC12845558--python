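"""Neural-network modules over the :mod:`tgsr.nn.tensor` autodiff core.

Modules register parameters and submodules by attribute assignment, expose
``named_parameters``/``state_dict`` in the familiar style, and record their
last input/output shapes during forward so the profiler can count
multiply-accumulates without a separate shape-inference pass.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "in_shape", None)
        object.__setattr__(self, "out_shape", None)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mname, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{mname}.{pname}" if mname else pname), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data
        for mname, mod in self.named_modules():
            for bname, b in mod._buffers.items():
                out[f"{mname}.{bname}" if mname else bname] = b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mname, mod in self.named_modules():
            for bname in mod._buffers:
                buffers[f"{mname}.{bname}" if mname else bname] = (mod, bname)
        for key, value in state.items():
            if key in params:
                params[key].data[...] = value
            elif key in buffers:
                mod, bname = buffers[key]
                arr = mod._buffers[bname]
                arr[...] = value
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        object.__setattr__(self, "in_shape", tuple(x.shape))
        out = self.forward(x)
        object.__setattr__(self, "out_shape", tuple(out.shape))
        return out


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Grouped 2-D convolution, optionally bias-free (the BN-followed case)."""

    def __init__(self, cin: int, cout: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_out = kernel * kernel * cout // groups
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            rng.normal(0.0, std, (cout, cin // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups
        self.kernel, self.cin, self.cout = kernel, cin, cout

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))
        self.momentum, self.eps = momentum, eps
        self.channels = channels

    def forward(self, x):
        return T.batch_norm(
            x, self.weight, self.bias, running_mean=self.running_mean,
            running_var=self.running_var, training=self.training,
            momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, cin: int, cout: int, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, 0.01, (cin, cout)))
        self.bias = Parameter(np.zeros(cout))
        self.cin, self.cout = cin, cout

    def forward(self, x):
        return T.add(T.matmul(x, self.weight), self.bias)


class _Activation(Module):
    fn = staticmethod(lambda x: x)

    def forward(self, x):
        return self.fn(x)


class ReLU(_Activation):
    fn = staticmethod(T.relu)


class GELU(_Activation):
    fn = staticmethod(T.gelu)


class Hardswish(_Activation):
    fn = staticmethod(T.hardswish)


class Hardsigmoid(_Activation):
    fn = staticmethod(T.hardsigmoid)


class Sigmoid(_Activation):
    fn = staticmethod(T.sigmoid)


class MaxPool2x2(Module):
    """2x2 stride-2 max pooling (the adaptive residual downsampler)."""

    def forward(self, x):
        return T.maxpool2x2(x)


class GlobalAvgPool(Module):
    """Average over both spatial axes, keeping 1x1 spatial dims."""

    def forward(self, x):
        return T.tmean(x, axis=(2, 3), keepdims=True)


class DirectionalAvgPool(Module):
    """Average over a single spatial axis (2 = height, 3 = width)."""

    def __init__(self, axis: int):
        super().__init__()
        self.axis = axis

    def forward(self, x):
        return T.tmean(x, axis=self.axis, keepdims=True)


class Dropout(Module):
    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return T.dropout(x, self.rate, self.rng, self.training)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
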