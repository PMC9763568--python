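from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = ["Param", "Layer", "Sequential"]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base class: ``forward`` caches what ``backward`` needs.

    ``backward`` consumes the gradient w.r.t. the forward output and
    returns the gradient w.r.t. the forward input, accumulating parameter
    gradients in place.
    """

    training: bool = True

    def params(self) -> Iterator[Param]:
        return iter(())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def train(self, mode: bool = True) -> "Layer":
        self.training = mode
        return self

    def eval(self) -> "Layer":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> Iterator[Param]:
        for layer in self.layers:
            yield from layer.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def train(self, mode: bool = True) -> "Sequential":
        self.training = mode
        for layer in self.layers:
            layer.train(mode)
        return self
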