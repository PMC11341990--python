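"""Neural-network module system: layers with parameters and train/eval state.

Initialisation draws from a process-wide generator set with :func:`seed_all`,
mirroring the global-RNG convention of the major frameworks, so a single seed
makes model construction reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the global generator used by all parameter initialisers."""
    global _rng
    _rng = np.random.default_rng(seed)


def _init_conv(shape, fan_in):
    return (_rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *a, **k):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *a, **k):
        return self.forward(*a, **k)

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for it in v:
                    if isinstance(it, Module):
                        yield it

    def modules(self):
        yield self
        for c in self._children():
            yield from c.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                items = v if isinstance(v, (list, tuple)) else (v,)
                for it in items:
                    if isinstance(it, Parameter) and id(it) not in seen:
                        seen.add(id(it))
                        yield it

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + name] = v.data
            elif isinstance(v, np.ndarray):
                out[prefix + name] = v
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for i, it in enumerate(v):
                    if isinstance(it, Module):
                        out.update(it.state_dict(f"{prefix}{name}.{i}."))
                    elif isinstance(it, Parameter):
                        out[f"{prefix}{name}.{i}"] = it.data
        return out

    def load_state_dict(self, sd: dict, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data = sd[prefix + name].astype(np.float32).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = sd[prefix + name]
            elif isinstance(v, Module):
                v.load_state_dict(sd, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, it in enumerate(v):
                    if isinstance(it, Module):
                        it.load_state_dict(sd, f"{prefix}{name}.{i}.")
                    elif isinstance(it, Parameter):
                        it.data = sd[f"{prefix}{name}.{i}"].astype(
                            np.float32).reshape(it.data.shape)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=None, groups=1, bias=True):
        super().__init__()
        if p is None:
            p = k // 2
        self.c1, self.c2, self.k, self.s, self.p, self.groups = c1, c2, k, s, p, groups
        self.weight = Parameter(_init_conv((c2, c1 // groups, k, k), c1 // groups * k * k))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, stride=self.s, padding=self.p,
                        groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            out, mu, var = x.batchnorm_train(self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        scale = self.weight.data / np.sqrt(self.running_var + self.eps)
        shift = self.bias.data - self.running_mean * scale
        return x * Tensor(scale.reshape(1, -1, 1, 1)) + Tensor(
            shift.reshape(1, -1, 1, 1))


class LayerNorm(Module):
    """Normalisation over the trailing (channel) axis of token tensors."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class Linear(Module):
    def __init__(self, c1, c2, bias=True):
        super().__init__()
        self.c1, self.c2 = c1, c2
        self.weight = Parameter(_init_conv((c1, c2), c1))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MaxPool2d(Module):
    def __init__(self, k, s=None, p=0):
        super().__init__()
        self.k, self.s, self.p = k, s or k, p

    def forward(self, x):
        return x.maxpool2d(self.k, self.s, self.p)


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return x.upsample_nearest(self.scale)
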