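"""Dense networks and Adam on top of :mod:`cebp._autodiff`.

ELU multilayer perceptrons with Glorot-uniform initialization, and a
classic Adam optimizer whose weight decay enters as an L2 penalty added to
each gradient before the moment updates.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from ._autodiff import Tensor, zero_grads


class MLP:
    """Fully connected network: ``depth`` ELU hidden layers, linear output."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        width: int,
        depth: int,
        rng: np.random.Generator,
    ):
        self.in_dim, self.out_dim, self.width, self.depth = in_dim, out_dim, width, depth
        dims = [in_dim] + [width] * depth + [out_dim]
        self.weights: List[Tensor] = []
        self.biases: List[Tensor] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (d_in + d_out))
            W = rng.uniform(-bound, bound, size=(d_in, d_out))
            self.weights.append(Tensor(W, requires_grad=True))
            self.biases.append(Tensor(np.zeros(d_out), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if k < last:
                h = h.elu()
        return h

    @property
    def parameters(self) -> List[Tensor]:
        return self.weights + self.biases

    def copy_from(self, other: "MLP") -> None:
        """Overwrite this network's parameters with another's (same shape)."""
        for p, q in zip(self.parameters, other.parameters):
            if p.data.shape != q.data.shape:
                raise ValueError("architecture mismatch")
            p.data = q.data.copy()

    def state(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.parameters, state):
            p.data = s.copy()


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        zero_grads(self.params)

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
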