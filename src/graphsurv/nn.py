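"""Neural-network building blocks on top of :mod:`graphsurv.autodiff`.

Layers follow the familiar Module pattern: parameters are ``Tensor``s with
``requires_grad=True``, collected recursively for the optimizer and for
checkpointing. All initialisation is Glorot-uniform from an explicit
``numpy.random.Generator`` so that runs are reproducible on one device.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "MLP", "Dropout", "Adam",
    "glorot_uniform", "conv2d", "pad_hw",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    if len(shape) == 4:  # conv kernel (kh, kw, cin, cout)
        receptive = shape[0] * shape[1]
        fan_in, fan_out = receptive * shape[2], receptive * shape[3]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: child modules/parameters discovered from ``__dict__``."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for key, param in params.items():
            value = np.asarray(state[key], dtype=np.float64)
            if value.shape != param.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {value.shape} "
                    f"vs model {param.data.shape}")
            param.data = value

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(glorot_uniform(rng, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self._rng.random(x.shape) < keep
        return x * Tensor(mask / keep)


class MLP(Module):
    """Two affine layers with GELU, optional dropout (mixer-style block)."""

    def __init__(self, dim: int, rng: np.random.Generator, expansion: int = 2,
                 dropout: float = 0.0):
        self.fc1 = Linear(dim, expansion * dim, rng)
        self.fc2 = Linear(expansion * dim, dim, rng)
        self.drop = Dropout(dropout, rng) if dropout > 0 else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x).gelu()
        if self.drop is not None:
            h = self.drop(h)
        return self.fc2(h)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1) -> Tensor:
    """2-D convolution (valid padding) via gather + matmul.

    ``x``: (N, H, W, Cin); ``weight``: (kh, kw, Cin, Cout).
    """
    n, h, w, cin = x.shape
    kh, kw, cin_w, cout = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("kernel larger than input")
    rows = (np.arange(oh)[:, None, None, None] * stride + np.arange(kh)[None, None, :, None])
    cols = (np.arange(ow)[None, :, None, None] * stride + np.arange(kw)[None, None, None, :])
    flat_idx = (rows * w + cols).reshape(-1)  # (oh*ow*kh*kw,)
    x_flat = x.reshape(n, h * w, cin)
    gathered = x_flat[:, flat_idx, :]                      # (n, oh*ow*kh*kw, cin)
    patches = gathered.reshape(n * oh * ow, kh * kw * cin)
    w2 = weight.reshape(kh * kw * cin, cout)
    out = patches @ w2
    if bias is not None:
        out = out + bias
    return out.reshape(n, oh, ow, cout)


def pad_hw(x: Tensor, p: int) -> Tensor:
    """Zero-pad the two spatial axes of an (N, H, W, C) tensor by ``p``."""
    if p == 0:
        return x
    n, h, w, c = x.shape
    zr = Tensor(np.zeros((n, p, w, c)))
    x = concat([zr, x, zr], axis=1)
    zc = Tensor(np.zeros((n, h + 2 * p, p, c)))
    return concat([zc, x, zc], axis=2)


class Adam:
    """Adam with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self._t)
            vhat = self._v[i] / (1 - b2 ** self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
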