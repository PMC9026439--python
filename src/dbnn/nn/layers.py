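"""Parameterised layer modules built on the autodiff tape.

Each module owns its :class:`~dbnn.nn.autograd.Tensor` parameters and is
called with an input tensor plus a ``train`` flag; there is no global
mode state.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays (trainable and buffers) for checkpointing."""
        out = {}
        for k, v in vars(self).items():
            if isinstance(v, Tensor):
                out[k] = v.data
            elif isinstance(v, np.ndarray):
                out[k] = v
            elif isinstance(v, Module):
                for sk, sv in v.state_arrays().items():
                    out[f"{k}.{sk}"] = sv
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in vars(self).items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key]).astype(v.data.dtype).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                arr = np.asarray(state[key]).astype(v.dtype).reshape(v.shape)
                v[...] = arr
            elif isinstance(v, Module):
                v.load_state_arrays({sk[len(key) + 1:]: sv for sk, sv in state.items()
                                     if sk.startswith(key + ".")})


class Conv2d(Module):
    """3x3 'same' convolution, He-normal weights, zero biases."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float64):
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)
                                        ).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, pad=self.kernel // 2)


class BatchNorm2d(Module):
    def __init__(self, ch: int, dtype=np.float64, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, train, self.momentum, self.eps)


class Linear(Module):
    """Dense layer, He-normal weights, zero biases."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        std = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, std, (in_dim, out_dim)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)
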