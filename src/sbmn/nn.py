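"""Parameterized layers built on the autodiff core.

Weights are drawn from N(0, 1/fan_in) so pre-activations keep unit scale
regardless of layer width; biases start at zero.  Everything is float64 and
seeded through ``numpy.random.Generator`` for bitwise reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, is_dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class Linear:
    W: Tensor  # (d_in, d_out)
    b: Tensor  # (d_out,)

    @property
    def d_in(self) -> int:
        return self.W.shape[0]

    @property
    def d_out(self) -> int:
        return self.W.shape[1]

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.W), self.b)


def make_linear(rng: np.random.Generator, d_in: int, d_out: int,
                gain: float = 1.0) -> Linear:
    """``gain`` follows the He convention: sqrt(2) when a relu precedes or
    follows the layer, so activations keep unit variance through depth."""
    W = Tensor(rng.normal(0.0, gain / np.sqrt(d_in), size=(d_in, d_out)),
               requires_grad=True)
    b = Tensor(np.zeros(d_out), requires_grad=True)
    return Linear(W, b)


@dataclass
class MLP2:
    """Two-layer perceptron with a configurable nonlinearity between."""

    fc1: Linear
    fc2: Linear
    activation: str = "relu"

    def __call__(self, x):
        h = self.fc1(x)
        h = apply_activation(h, self.activation)
        return self.fc2(h)


def apply_activation(x, name: str):
    if name == "relu":
        return ad.relu(x)
    if name == "sigmoid":
        return ad.sigmoid(x)
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}")


def make_mlp2(rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int,
              activation: str = "relu") -> MLP2:
    # sqrt(2) gain on the hidden layer compensates the variance the
    # rectifier removes, keeping the block near-isometric at initialization
    g = np.sqrt(2.0) if activation == "relu" else 1.0
    return MLP2(make_linear(rng, d_in, d_hidden, gain=g),
                make_linear(rng, d_hidden, d_out), activation)


@dataclass
class PatchConv:
    """Convolution with kernel size equal to stride (non-overlapping patches).

    Input (B, C, S, S) -> output (B, O, S/p, S/p).  With kernel == stride the
    im2col step is a pure reshape, so forward and backward are exact tensor
    rearrangements plus one matmul.
    """

    W: Tensor  # (C * p * p, O)
    b: Tensor  # (O,)
    patch: int
    in_channels: int
    out_channels: int

    def __call__(self, x):
        B, C, S, _ = x.shape
        p = self.patch
        if C != self.in_channels or S % p != 0:
            raise ValueError(
                f"PatchConv expects {self.in_channels} channels and size "
                f"divisible by {p}; got {C} channels, size {S}")
        n = S // p
        # (B,C,n,p,n,p) -> (B,n,n,C,p,p) -> (B*n*n, C*p*p)
        cols = ad.reshape(x, (B, C, n, p, n, p))
        cols = ad.permute(cols, (0, 2, 4, 1, 3, 5))
        cols = ad.reshape(cols, (B * n * n, C * p * p))
        out = ad.add(ad.matmul(cols, self.W), self.b)
        out = ad.reshape(out, (B, n, n, self.out_channels))
        return ad.permute(out, (0, 3, 1, 2))


def make_patch_conv(rng: np.random.Generator, in_channels: int,
                    out_channels: int, patch: int) -> PatchConv:
    fan_in = in_channels * patch * patch
    W = Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, out_channels)),
               requires_grad=True)
    b = Tensor(np.zeros(out_channels), requires_grad=True)
    return PatchConv(W, b, patch, in_channels, out_channels)


def global_avg_pool(x):
    """(B, C, H, W) -> (B, C)."""
    return ad.tmean(ad.tmean(x, axis=3), axis=2)


def collect_params(obj) -> list[Tensor]:
    """Depth-first collection of trainable tensors from nested containers."""
    out: list[Tensor] = []
    seen: set[int] = set()

    def walk(o):
        if isinstance(o, Tensor):
            if o.requires_grad and id(o) not in seen:
                seen.add(id(o))
                out.append(o)
        elif is_dataclass(o) and not isinstance(o, type):
            for f in fields(o):
                walk(getattr(o, f.name))
        elif isinstance(o, (list, tuple)):
            for item in o:
                walk(item)
        elif isinstance(o, dict):
            for item in o.values():
                walk(item)

    walk(obj)
    return out


def zero_grads(params: list[Tensor]) -> None:
    for p in params:
        p.grad = None
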