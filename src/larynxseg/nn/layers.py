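"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor. ``decay`` marks it for weight decay (matrices
    yes, biases and norm gains no)."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init at ±2 std, the transformer convention."""
    x = rng.normal(0.0, std, size=shape)
    bound = 2.0 * std
    bad = np.abs(x) > bound
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > bound
    return x.astype(np.float32)


class Module:
    """Minimal module container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def walk(obj, prefix):
            if isinstance(obj, Parameter):
                out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.weight = Parameter(trunc_normal(rng, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim, dtype=np.float32), decay=False)
        self.bias = Parameter(np.zeros(dim, dtype=np.float32), decay=False)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gain, self.bias, self.eps)


class Conv2d(Module):
    """Strided 2-d convolution (used by the overlap patch embedding)."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int, padding: int):
        self.weight = Parameter(trunc_normal(rng, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32), decay=False)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv3x3(Module):
    def __init__(self, rng, channels: int):
        self.weight = Parameter(trunc_normal(rng, (channels, 3, 3)))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.dwconv3x3(x, self.weight, self.bias)


class AdamW:
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
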