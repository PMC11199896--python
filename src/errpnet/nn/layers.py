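"""Neural-network layers built on the autograd engine.

Layers follow the familiar module pattern: parameters are
gradient-carrying :class:`~errpnet.nn.autograd.Tensor` objects, every module
exposes ``named_parameters`` / ``state_dict`` / ``load_state_dict`` and a
train/eval mode switch (batch-norm running statistics, dropout).
Weight initialization is drawn from a generator passed in explicitly so a
build is fully determined by its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, norm_affine


class Module:
    """Base class: child discovery, parameter iteration, mode switching."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out["buffer:" + name] = np.asarray(buf).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._set_buffer_by_path(name[len("buffer:"):], np.asarray(value))
            else:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = path.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]] = value
        object.__setattr__(mod, parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Conv2d(Module):
    """Valid-mode stride-1 2-D convolution."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel_size
        fan_in = in_channels * kh * kw
        self.weight = _param(rng, (out_channels, in_channels, kh, kw), fan_in)
        self.bias = _param(rng, (out_channels,), fan_in)
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel with running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * unbiased
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            return norm_affine(x, g, b, (0, 2, 3), self.eps)
        mu = self.running_mean.reshape(1, -1, 1, 1)
        var = self.running_var.reshape(1, -1, 1, 1)
        xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        return xhat * g + b


class AvgPool2d(Module):
    """Non-overlapping average pooling (stride = kernel)."""

    def __init__(self, kernel_size: tuple[int, int]):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel_size
        b, c, h, w = x.shape
        if h % kh or w % kw:
            raise ValueError(f"pool {self.kernel_size} does not divide ({h}, {w})")
        x = x.reshape(b, c, h // kh, kh, w // kw, kw)
        return x.mean(axis=(3, 5))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng, (in_features, out_features), in_features)
        self.bias = _param(rng, (out_features,), in_features)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    The mask is drawn from the generator passed at call time by the training
    loop so a whole run is reproducible from one seed.
    """

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a generator")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x.dropout_mask(mask)


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return norm_affine(x, self.gamma, self.beta, (x.ndim - 1,), self.eps)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        q = self._split(self.wq(x), b, t)
        k = self._split(self.wk(x), b, t)
        v = self._split(self.wv(x), b, t)
        scores = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        ctx = attn.matmul(v)  # (B, H, T, dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, t, self.d_model)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder layer.

    ``x -> LN(x + MHSA(x)) -> LN(· + FFN(·))`` with a ReLU feed-forward of
    width ``ffn_dim``.  No positional encoding is applied by the layer; the
    token sequences it sees here have length two and carry order information
    injected by the preceding convolutions.
    """

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)
        self.norm2 = LayerNorm(d_model)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x + self.attn(x))
        return self.norm2(h + self.ffn2(self.ffn1(h).relu()))
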