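"""Dual-branch convolution + transformer-encoder ErrP classifier.

Two parallel feature extractors consume the same (B, 1, 2, 64) epoch batch:

* **FE-E** (electrode branch) treats the two electrodes as a length-2 token
  sequence.  Conv (1, 33) x64 filters -> BN -> ReLU -> AvgPool (1, 4) ->
  Conv (1, 8) -> BN -> ReLU collapses each electrode's time course to a
  64-feature embedding; a 4-head transformer encoder layer then models the
  inter-electrode correlation.
* **FE-T** (temporal branch) treats sampling points as the sequence.  Conv
  (2, 33) x64 filters collapses the electrode axis, AvgPool (1, 16) reduces
  the 32 remaining time positions to 2 tokens of 64 features, and a second
  transformer encoder layer models their interaction.

Each branch adds its encoder input back onto the encoder output (an outer
residual, on top of the encoder's internal ones) and layer-normalizes.  The
two (2, 64) token maps are concatenated to (4, 64), flattened to 256 and
classified through 256 -> 64 -> 2 fully connected layers with dropout after
each, ending in a softmax (class 0 = correct, class 1 = error).

The expected shape chain for the default configuration::

    FE-E: (B,1,2,64) -conv-> (B,64,2,32) -pool-> (B,64,2,8) -conv-> (B,64,2,1)
          -tokens-> (B,2,64) -encoder+residual+LN-> (B,2,64)
    FE-T: (B,1,2,64) -conv-> (B,64,1,32) -pool-> (B,64,1,2)
          -tokens-> (B,2,64) -encoder+residual+LN-> (B,2,64)
    head: concat -> (B,4,64) -flatten-> (B,256) -> (B,64) -> (B,2)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "ErrPNet", "build", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Declarative architecture description."""

    n_channels: int = 2
    n_samples: int = 64
    conv_filters: int = 64
    fe_e_kernel1: tuple[int, int] = (1, 33)
    fe_e_pool: tuple[int, int] = (1, 4)
    fe_e_kernel2: tuple[int, int] = (1, 8)
    fe_t_kernel: tuple[int, int] = (2, 33)
    fe_t_pool: tuple[int, int] = (1, 16)
    d_model: int = 64
    n_heads: int = 4
    ffn_dim: int = 256
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        w1 = self.n_samples - self.fe_e_kernel1[1] + 1
        if w1 % self.fe_e_pool[1]:
            raise ValueError(f"FE-E pool width {self.fe_e_pool[1]} does not divide {w1}")
        w2 = w1 // self.fe_e_pool[1] - self.fe_e_kernel2[1] + 1
        if w2 != 1:
            raise ValueError("FE-E second conv must reduce the temporal width to 1")
        wt = self.n_samples - self.fe_t_kernel[1] + 1
        if wt % self.fe_t_pool[1]:
            raise ValueError(f"FE-T pool width {self.fe_t_pool[1]} does not divide {wt}")
        if wt // self.fe_t_pool[1] != self.n_channels:
            raise ValueError("FE-T pooling must reduce time positions to the channel count")
        if self.fe_t_kernel[0] != self.n_channels:
            raise ValueError("FE-T kernel must span all channels")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.conv_filters != self.d_model:
            raise ValueError("conv_filters must equal d_model (tokens are filter vectors)")

    @property
    def fusion_width(self) -> int:
        n_tokens = self.n_channels + (self.n_samples - self.fe_t_kernel[1] + 1) // self.fe_t_pool[1]
        return n_tokens * self.d_model

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        raw = dict(raw)
        for key in ("fe_e_kernel1", "fe_e_pool", "fe_e_kernel2", "fe_t_kernel", "fe_t_pool"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**raw)


class ErrPNet(nn.Module):
    """The instantiated dual-branch network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c = config
        self.fe_e_conv1 = nn.Conv2d(1, c.conv_filters, c.fe_e_kernel1, rng)
        self.fe_e_bn1 = nn.BatchNorm2d(c.conv_filters)
        self.fe_e_pool = nn.AvgPool2d(c.fe_e_pool)
        self.fe_e_conv2 = nn.Conv2d(c.conv_filters, c.conv_filters, c.fe_e_kernel2, rng)
        self.fe_e_bn2 = nn.BatchNorm2d(c.conv_filters)
        self.fe_e_encoder = nn.TransformerEncoderLayer(c.d_model, c.n_heads, c.ffn_dim, rng)
        self.fe_e_norm = nn.LayerNorm(c.d_model)
        self.fe_t_conv = nn.Conv2d(1, c.conv_filters, c.fe_t_kernel, rng)
        self.fe_t_bn = nn.BatchNorm2d(c.conv_filters)
        self.fe_t_pool = nn.AvgPool2d(c.fe_t_pool)
        self.fe_t_encoder = nn.TransformerEncoderLayer(c.d_model, c.n_heads, c.ffn_dim, rng)
        self.fe_t_norm = nn.LayerNorm(c.d_model)
        self.fc1 = nn.Linear(c.fusion_width, c.d_model, rng)
        self.drop1 = nn.Dropout(c.dropout_rate)
        self.fc2 = nn.Linear(c.d_model, c.n_classes, rng)
        self.drop2 = nn.Dropout(c.dropout_rate)

    # -- branches -------------------------------------------------------------

    def forward_fe_e(self, x: Tensor, trace: dict | None = None) -> Tensor:
        """Electrode branch: (B, 1, C, T) -> (B, C, d_model) token map."""
        h = self.fe_e_bn1(self.fe_e_conv1(x)).relu()
        if trace is not None:
            trace["fe_e.conv1"] = h.shape
        h = self.fe_e_pool(h)
        if trace is not None:
            trace["fe_e.pool"] = h.shape
        h = self.fe_e_bn2(self.fe_e_conv2(h)).relu()
        if trace is not None:
            trace["fe_e.conv2"] = h.shape
        b, f, c, _ = h.shape
        tokens = h.reshape(b, f, c).transpose(0, 2, 1)  # electrodes as tokens
        if trace is not None:
            trace["fe_e.tokens"] = tokens.shape
        out = self.fe_e_norm(tokens + self.fe_e_encoder(tokens))
        if trace is not None:
            trace["fe_e.out"] = out.shape
        return out

    def forward_fe_t(self, x: Tensor, trace: dict | None = None) -> Tensor:
        """Temporal branch: (B, 1, C, T) -> (B, C, d_model) token map."""
        h = self.fe_t_bn(self.fe_t_conv(x)).relu()
        if trace is not None:
            trace["fe_t.conv"] = h.shape
        h = self.fe_t_pool(h)
        if trace is not None:
            trace["fe_t.pool"] = h.shape
        b, f, _, t = h.shape
        tokens = h.reshape(b, f, t).transpose(0, 2, 1)  # time positions as tokens
        if trace is not None:
            trace["fe_t.tokens"] = tokens.shape
        out = self.fe_t_norm(tokens + self.fe_t_encoder(tokens))
        if trace is not None:
            trace["fe_t.out"] = out.shape
        return out

    def forward_logits(self, x: Tensor, rng: np.random.Generator | None = None,
                       trace: dict | None = None) -> Tensor:
        fe_e = self.forward_fe_e(x, trace)
        fe_t = self.forward_fe_t(x, trace)
        fused = nn.concat([fe_e, fe_t], axis=1)  # FE-E tokens first
        if trace is not None:
            trace["fusion"] = fused.shape
        b = fused.shape[0]
        flat = fused.reshape(b, self.config.fusion_width)
        if trace is not None:
            trace["flatten"] = flat.shape
        h = self.drop1(self.fc1(flat), rng)
        if trace is not None:
            trace["fc1"] = h.shape
        logits = self.drop2(self.fc2(h), rng)
        if trace is not None:
            trace["fc2"] = logits.shape
        return logits

    def forward(self, x, rng: np.random.Generator | None = None,
                trace: dict | None = None) -> Tensor:
        """Class probabilities (B, 2); rows sum to one."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 4 or x.shape[1:] != (1, self.config.n_channels, self.config.n_samples):
            raise ValueError(
                f"expected (B, 1, {self.config.n_channels}, {self.config.n_samples}), got {x.shape}")
        probs = self.forward_logits(x, rng, trace).softmax(axis=-1)
        if trace is not None:
            trace["probs"] = probs.shape
        return probs

    def predict_proba(self, epochs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode error-class probabilities for (n, 2, 64) epochs."""
        was_training = self.training
        self.eval()
        epochs = np.asarray(epochs, dtype=np.float64)[:, None, :, :]
        out = [self.forward(Tensor(chunk)).data
               for chunk in np.array_split(epochs, max(1, -(-len(epochs) // batch_size)))]
        self.train(was_training)
        return np.concatenate(out)

    def clone(self) -> "ErrPNet":
        twin = ErrPNet(self.config, self.seed)
        twin.load_state_dict(self.state_dict())
        twin.train(self.training)
        return twin

    def trace_shapes(self, batch_size: int = 8, rng: np.random.Generator | None = None) -> dict:
        """Run a probe batch through the net and record intermediate shapes."""
        rng = rng or np.random.default_rng(0)
        x = rng.standard_normal((batch_size, 1, self.config.n_channels, self.config.n_samples))
        was_training = self.training
        self.eval()
        trace: dict = {"input": x.shape}
        self.forward(Tensor(x), trace=trace)
        self.train(was_training)
        return trace


def build(config: ModelConfig = ModelConfig(), seed: int = 0) -> ErrPNet:
    """Instantiate a network with seed-deterministic initial weights."""
    return ErrPNet(config, seed)


def count_parameters(net: ErrPNet) -> int:
    """Total trainable scalar count."""
    return int(sum(p.data.size for p in net.parameters()))


def save_checkpoint(net: ErrPNet, path: str | Path) -> None:
    """Single-file checkpoint: weights + config + seed; reload is bit-exact."""
    state = net.state_dict()
    meta = json.dumps({"config": dataclasses.asdict(net.config), "seed": net.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> ErrPNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    net = ErrPNet(ModelConfig.from_dict(meta["config"]), meta["seed"])
    net.load_state_dict(state)
    return net
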