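"""Parameterized layers and containers built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, conv2d


class Module:
    training: bool = True

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def train(self) -> None:
        self.set_training(True)

    def eval(self) -> None:
        self.set_training(False)

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats), in a
        deterministic traversal order."""
        out: list[np.ndarray] = []
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        if isinstance(self, BatchNorm2d):
            out.extend([self.running_mean, self.running_var])
        return out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {str(i): p.data.copy() for i, p in enumerate(self.parameters())}
        for i, b in enumerate(self.buffers()):
            state[f"b{i}"] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        bufs = self.buffers()
        if len(state) != len(params) + len(bufs):
            raise ValueError(
                f"state has {len(state)} arrays, model has "
                f"{len(params)} parameters + {len(bufs)} buffers")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()
        for i, b in enumerate(bufs):
            b[...] = np.asarray(state[f"b{i}"], dtype=b.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            fan_in = in_ch * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import _node

        data = x.data
        if self.training:
            mu = data.mean(axis=(0, 2, 3))
            var = data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu = self.running_mean.astype(DTYPE)
            var = self.running_var.astype(DTYPE)
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (data - mu.astype(DTYPE)[None, :, None, None]) \
            / std[None, :, None, None]
        y = (self.gamma.data[None, :, None, None] * xhat
             + self.beta.data[None, :, None, None])
        out = _node(y, (x, self.gamma, self.beta))
        training = self.training

        def bwd(g):
            self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            self.beta._accumulate(g.sum(axis=(0, 2, 3)))
            gs = self.gamma.data[None, :, None, None] / std[None, :, None, None]
            if training:
                n = g.shape[0] * g.shape[2] * g.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = gs * (g - gsum / n - xhat * gxsum / n)
            else:
                gx = gs * g
            x._accumulate(gx)

        out._backward = bwd
        return out


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_f, out_f)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
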