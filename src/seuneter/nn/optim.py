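from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["RMSprop"]


class RMSprop:
    """RMSprop with the conventional square-gradient moving average.

    ``alpha`` is the smoothing constant of the squared-gradient estimate;
    ``eps`` stabilizes the division.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-5,
        alpha: float = 0.99,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = list(params)
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.square_avg = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, sq in zip(self.params, self.square_avg):
            sq *= self.alpha
            sq += (1.0 - self.alpha) * p.grad * p.grad
            p.data -= self.lr * p.grad / (np.sqrt(sq) + self.eps)
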