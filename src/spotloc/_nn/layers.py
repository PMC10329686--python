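"""Parameterized layers built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Parameter", "Linear", "Conv2d", "ConvTranspose2d", "collect_params"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(_kaiming(rng, in_features, (out_features,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def params(self):
        return [self.weight, self.bias]


class Conv2d:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, padding: int = 1):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(_kaiming(rng, fan_in, (out_ch,)))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)

    def params(self):
        return [self.weight, self.bias]


class ConvTranspose2d:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, padding: int = 1,
                 output_padding: int = 1):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(_kaiming(rng, fan_in, (out_ch,)))
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding,
                                  output_padding=self.output_padding)

    def params(self):
        return [self.weight, self.bias]


def collect_params(*layers) -> list[Parameter]:
    out: list[Parameter] = []
    for layer in layers:
        out.extend(layer.params())
    return out
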