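"""Neural-network layers built on the autograd engine.

Conventions follow common GAN practice: weights are drawn from N(0, 0.02),
spectral normalization constrains the top singular value of a weight matrix
via one power-iteration step per forward pass, and batch normalization keeps
exponential running statistics for evaluation mode.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m._training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m._training = False
        return self

    @property
    def training(self) -> bool:
        return getattr(self, "_training", True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    # state dict: flat {name: array} using deterministic traversal order
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(m._buffers())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        n = len(params)
        for p, a in zip(params, arrays[:n]):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.astype(_DTYPE).copy()
        i = n
        for m in self.modules():
            bufs = m._buffers()
            for b in bufs:
                b[...] = arrays[i]
                i += 1

    def _buffers(self) -> list[np.ndarray]:
        return []

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, spectral_norm: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(rng.normal(0.0, 0.02, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.spectral_norm = spectral_norm
        if spectral_norm:
            c_flat = c_in * kernel * kernel
            self._u = rng.normal(size=c_out).astype(_DTYPE)
            self._u /= np.linalg.norm(self._u) + 1e-12
            self._v = rng.normal(size=c_flat).astype(_DTYPE)
            self._v /= np.linalg.norm(self._v) + 1e-12

    def _buffers(self):
        return [self._u, self._v] if self.spectral_norm else []

    def _normalized_weight(self) -> Tensor:
        # One power-iteration step on the (O, C*k*k) unfolding per training
        # forward; u, v are buffers, treated as constants in the gradient
        # (standard convention) and frozen in evaluation mode.
        wmat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        if self.training:
            v = wmat.T @ self._u
            v /= np.linalg.norm(v) + 1e-12
            u = wmat @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u[...] = u
            self._v[...] = v
        uv = np.outer(self._u, self._v).reshape(self.weight.data.shape)
        sigma = (self.weight * Tensor(uv)).sum()
        return self.weight * sigma.pow(-1.0)

    def __call__(self, x: Tensor) -> Tensor:
        w = self._normalized_weight() if self.spectral_norm else self.weight
        return conv2d(x, w, self.bias, stride=self.stride, padding=self.padding)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 spectral_norm: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None
        self.spectral_norm = spectral_norm
        if spectral_norm:
            self._u = rng.normal(size=n_out).astype(_DTYPE)
            self._u /= np.linalg.norm(self._u) + 1e-12
            self._v = rng.normal(size=n_in).astype(_DTYPE)
            self._v /= np.linalg.norm(self._v) + 1e-12

    def _buffers(self):
        return [self._u, self._v] if self.spectral_norm else []

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weight
        if self.spectral_norm:
            wmat = self.weight.data.T  # (n_out, n_in)
            if self.training:
                v = wmat.T @ self._u
                v /= np.linalg.norm(v) + 1e-12
                u = wmat @ v
                u /= np.linalg.norm(u) + 1e-12
                self._u[...] = u
                self._v[...] = v
            uv = np.outer(self._v, self._u)  # (n_in, n_out)
            sigma = (self.weight * Tensor(uv)).sum()
            w = self.weight * sigma.pow(-1.0)
        y = x.matmul(w)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu).pow(2.0)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) * (var + Tensor(np.float32(self.eps))).pow(-0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class GLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.glu()


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.alpha)


class Tanh(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.tanh()


class Upsample2x(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.upsample2x()


class NoiseInjection(Module):
    """Adds learned-amplitude Gaussian spatial noise (per feature map)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.weight = Parameter(np.zeros((1, channels, 1, 1)))
        self._rng = rng or np.random.default_rng()

    def reseed(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        b, _, h, w = x.data.shape
        noise = self._rng.standard_normal((b, 1, h, w)).astype(_DTYPE)
        return x + self.weight * Tensor(noise)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
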