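"""Trainable building blocks: linear maps, layer normalization, MLPs, Adam."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "MLP", "Dropout", "Adam"]


class Module:
    """Base class: parameter registry plus train/eval mode switching."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list["Module"] = []
        self.training = True

    def register(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def add_param(self, value: np.ndarray) -> Tensor:
        p = Tensor(value, requires_grad=True)
        self._params.append(p)
        return p

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for c in self._children:
            c.set_training(flag)

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters + buffers), in a stable order."""
        out = [p.value for p in self._params] + self.buffers()
        for c in self._children:
            out.extend(c.state_arrays())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)

        def _load(m: Module):
            for p in m._params:
                src = next(it)
                if p.value.shape != src.shape:
                    raise ValueError("checkpoint shape mismatch")
                p.value = src.copy()
            m.load_buffers(it)
            for c in m._children:
                _load(c)

        _load(self)

    def buffers(self) -> list[np.ndarray]:
        return []

    def load_buffers(self, it) -> None:
        pass


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = self.add_param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = self.add_param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Per-point normalization across the channel axis.

    Normalizes each point's feature vector to zero mean / unit variance with
    learned scale and shift.  Unlike batch statistics this is independent of
    batch composition, so evaluation is deterministic point by point, and
    the backward pass is exact.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones(n_channels))
        self.beta = self.add_param(np.zeros(n_channels))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.value.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class MLP(Module):
    """Shared pointwise MLP: [Linear -> LayerNorm -> ReLU] per width."""

    def __init__(self, n_in: int, widths, rng: np.random.Generator, norm: bool = True):
        super().__init__()
        self.layers: list[tuple[Linear, LayerNorm | None]] = []
        for w in widths:
            lin = self.register(Linear(n_in, w, rng))
            bn = self.register(LayerNorm(w)) if norm else None
            self.layers.append((lin, bn))
            n_in = w
        self.n_out = n_in

    def __call__(self, x: Tensor) -> Tensor:
        for lin, bn in self.layers:
            x = lin(x)
            if bn is not None:
                x = bn(x)
            x = x.relu()
        return x


class Adam:
    """Adaptive-moment optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

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
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
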