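"""Layer/module system: parameter containers over the autodiff tensors.

Mirrors the familiar ``Module`` idiom: submodules and parameters registered
by attribute assignment, ``parameters()`` / ``state_dict()`` traversal,
``train()``/``eval()`` modes.  All layers run on either real tensors or
profiling shadows (see :mod:`bbyolo.nn.functional`).
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity", "Conv2d", "Conv1d", "BatchNorm2d",
    "Linear", "MaxPool2d", "Upsample", "ConvBnAct", "ACTIVATIONS", "seed_rng",
]

# module-level RNG for weight initialisation; reseed for reproducible builds
_RNG = np.random.default_rng(0)


def seed_rng(seed: int):
    """Reseed the weight-initialisation RNG (call before building a model)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


ACTIVATIONS = {
    "relu": lambda x: x.relu(),
    "silu": lambda x: x.silu(),
    "hswish": lambda x: x.hswish(),
    "mish": lambda x: x.mish(),
    "sigmoid": lambda x: x.sigmoid(),
    "identity": lambda x: x,
}


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ---------------------------------------------------
    def state_dict(self, prefix=""):
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, b in self._buffers.items():
            out[prefix + k] = b
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state, prefix=""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=p.data.dtype).reshape(p.data.shape)
        for k in list(self._buffers):
            arr = self._buffers[k]
            arr[...] = np.asarray(state[prefix + k]).reshape(arr.shape)
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def __iter__(self):
        return iter(self._seq)

    def __len__(self):
        return len(self._seq)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, bias=True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        kh = kw = int(kernel_size)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = in_channels // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(
            _RNG.uniform(-bound, bound, (out_channels, in_channels // groups, kh, kw)
                         ).astype(np.float32), requires_grad=True)
        self.bias = (Tensor(_RNG.uniform(-bound, bound, out_channels).astype(np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class Conv1d(Module):
    """1-D convolution over the last axis of an (N, C, L) input."""

    def __init__(self, in_channels, out_channels, kernel_size, padding=None, bias=True):
        super().__init__()
        k = int(kernel_size)
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(
            _RNG.uniform(-bound, bound, (out_channels, in_channels, 1, k)).astype(np.float32),
            requires_grad=True)
        self.bias = (Tensor(_RNG.uniform(-bound, bound, out_channels).astype(np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x):
        # lift to NCHW with H=1, pad only along L
        if isinstance(x, F.Shadow):
            x4 = F.Shadow((x.shape[0], x.shape[1], 1, x.shape[2]), x.counter)
        else:
            n, c, L = x.shape
            x4 = x.reshape(n, c, 1, L)
        out = F.conv2d(x4, self.weight, self.bias, padding=(0, self.padding))
        return out.reshape(out.shape[0], out.shape[1], out.shape[3])


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x):
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(
            _RNG.uniform(-bound, bound, (out_features, in_features)).astype(np.float32),
            requires_grad=True)
        self.bias = (Tensor(_RNG.uniform(-bound, bound, out_features).astype(np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride or kernel_size, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)


class ConvBnAct(Module):
    """conv (no bias) + batch norm + activation — the YOLO "Conv" unit."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, d=1, act="silu"):
        super().__init__()
        if p is None:
            p = (k - 1) // 2 * d  # 'same' for odd kernels
        self.conv = Conv2d(c1, c2, k, s, p, d, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act_name = act
        self._act = ACTIVATIONS[act]

    def forward(self, x):
        return self._act(self.bn(self.conv(x)))
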