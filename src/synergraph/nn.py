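"""Network building blocks: linear layers, batch normalization, dropout,
perceptron stacks and the Adam optimizer.

All parameters are :class:`~synergraph.autodiff.Tensor` objects with
``requires_grad=True``; a module exposes them through :meth:`Module.parameters`
so the trainer can hand them to :class:`Adam`.  Initialization is fully seeded
through a ``numpy.random.Generator`` for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "Dropout", "MLP", "Adam"]


class Module:
    """Base class: parameter collection + train/eval mode switching."""

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
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def set_training(self, mode: bool) -> None:
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)
        if hasattr(self, "training"):
            self.training = mode

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Fan-average (Glorot) uniform initialization."""
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(glorot(rng, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis.

    In training mode statistics come from the current batch and the running
    estimates are updated; in evaluation mode the running estimates are used,
    which makes inference deterministic and batch-size independent.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps) ** 0.5
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout with an explicitly seeded mask stream."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self.training = True

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class MLP(Module):
    """A perceptron stack: affine -> batch-norm -> ReLU (-> dropout) per hidden
    layer, plus a final affine.  Covers both the two-layer modality projectors
    and the three-layer prediction head."""

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        dropout: float = 0.0,
        batch_norm: bool = True,
    ):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers: list[Module] = []
        for k in range(len(sizes) - 1):
            self.layers.append(Linear(sizes[k], sizes[k + 1], rng))
            if k < len(sizes) - 2:  # hidden layers only
                if batch_norm:
                    self.layers.append(BatchNorm1d(sizes[k + 1]))
                self.layers.append(_Relu())
                if dropout > 0:
                    self.layers.append(Dropout(dropout, rng))

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class _Relu(Module):
    def forward(self, x):
        from .autodiff import relu

        return relu(x)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
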