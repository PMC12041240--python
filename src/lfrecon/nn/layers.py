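"""Network building blocks on top of the autodiff core: convolutions,
batch normalization, dense heads, and the AdamW optimizer."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Base class with parameter bookkeeping and train/eval switching."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, child in self._children.items():
            out.update(child.buffers(prefix + name + "."))
        return out

    def load_buffers(self, values: dict[str, np.ndarray], prefix: str = ""):
        for k in list(self._buffers):
            self._buffers[k] = values[prefix + k].copy()
        for name, child in self._children.items():
            child.load_buffers(values, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters().values()))


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.w = self.add_param("w", rng.normal(0, scale, (c_out, c_in, k, k)))
        self.b = self.add_param("b", np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("gamma", np.ones(c))
        self.beta = self.add_param("beta", np.zeros(c))
        self._buffers["running_mean"] = np.zeros(c)
        self._buffers["running_var"] = np.ones(c)

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel())
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return g * xhat + b


class ConvBlock(Module):
    """3×3 convolution + batch normalization + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv = self.add_child("conv", Conv2d(c_in, c_out, 3, rng, stride))
        self.bn = self.add_child("bn", BatchNorm2d(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Dense(Module):
    """Fully connected layer on (B, C) inputs (a 1×1 convolution after
    global pooling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.w = self.add_param("w", rng.normal(0, scale, (c_in, c_out)))
        self.b = self.add_param("b", np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class AdamW:
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
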