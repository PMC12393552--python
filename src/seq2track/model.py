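"""Model assembly: convolutional stem/tower, attention stack, cropping,
optional final pointwise layer, and a linear head with softplus rates.

The network maps a one-hot DNA sequence of length ``sequence_length`` to a
``(output_bins, num_tracks)`` matrix of strictly positive Poisson rates at
``bin_size`` resolution. Structure follows the simplified variant adopted
here: ablation flags *remove* layers structurally (the parameters do not
exist), rather than zeroing them out.

Width schedule: the stem runs at ``model_width // 2`` channels and the
tower grows geometrically to ``model_width``; each of the first
``num_pooling_stages`` convolutional blocks is followed by a factor-2
pooling stage so that positions after the tower sit exactly at one per
``bin_size`` base pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, List, Optional

import numpy as np

from . import nn
from .config import ArchitectureConfig
from .errors import ConfigurationError, ShapeError
from .nn import (
    AttentionPool,
    CenterCrop,
    Conv1d,
    Dropout,
    GELU,
    LayerNorm,
    Linear,
    MaxPool,
    Module,
    MultiHeadAttention,
    Param,
    Residual,
    Sequential,
    Softplus,
)

__all__ = [
    "Model",
    "build_model",
    "count_parameters",
    "param_checksum",
]


def _tower_widths(cfg: ArchitectureConfig) -> List[int]:
    """Channel width after each conv block: stem at half width, geometric
    growth to ``model_width`` by the last block."""
    n = cfg.num_conv_blocks
    if n == 1:
        return [cfg.model_width]
    w0 = max(1, cfg.model_width // 2)
    w1 = cfg.model_width
    widths = [round(w0 * (w1 / w0) ** (i / (n - 1))) for i in range(n)]
    widths[-1] = w1
    return widths


def _make_pool(name: str, cfg: ArchitectureConfig, c: int) -> Module:
    if cfg.pooling_type == "attention":
        return AttentionPool(name, c)
    return MaxPool()


def _ffn(name: str, cfg: ArchitectureConfig, rng) -> Module:
    """Position-wise feed-forward sub-block (pre-norm, residual applied by
    caller). Removing the attention-block linear at the ``ffn_second`` site
    collapses the expansion to a single width-preserving linear layer."""
    c = cfg.model_width
    drop_ffn = not cfg.use_attention_linear and cfg.attention_linear_site == "ffn_second"
    if drop_ffn:
        layers = [LayerNorm(f"{name}.ln", c), Linear(f"{name}.lin", c, c, rng), GELU()]
    else:
        layers = [
            LayerNorm(f"{name}.ln", c),
            Linear(f"{name}.lin1", c, 2 * c, rng),
            GELU(),
            Dropout(cfg.dropout_rate),
            Linear(f"{name}.lin2", 2 * c, c, rng),
        ]
    return Sequential(layers)


class Model:
    """A built network: ordered trunk modules plus a linear head.

    ``forward`` consumes a ``(sequence_length, 4)`` one-hot matrix and
    returns a ``(output_bins, num_tracks)`` rate matrix. ``backward``
    consumes the gradient of a scalar loss with respect to the rates and
    accumulates parameter gradients.
    """

    def __init__(self, config: ArchitectureConfig, trunk: Sequential,
                 head: Linear, softplus: Softplus):
        self.config = config
        self.trunk = trunk
        self.head = head
        self.softplus = softplus

    # -- parameter access ------------------------------------------------
    def parameters(self, group: str = "all") -> Iterator[Param]:
        if group not in ("all", "trunk", "head"):
            raise ValueError(f"unknown parameter group: {group!r}")
        for p in self.trunk.parameters():
            if group in ("all", "trunk"):
                yield p
        for p in self.head.parameters():
            if group in ("all", "head"):
                yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- execution -------------------------------------------------------
    def forward_one(self, x: np.ndarray, *, train: bool = False,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 2 or x.shape != (self.config.sequence_length, 4):
            raise ShapeError(
                f"expected input of shape ({self.config.sequence_length}, 4), "
                f"got {x.shape}"
            )
        h = self.trunk.forward(x, train=train, rng=rng)
        h = self.head.forward(h, train=train, rng=rng)
        return self.softplus.forward(h, train=train, rng=rng)

    def forward(self, batch, *, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Run each encoding in ``batch`` independently (list in, list out)."""
        return [self.forward_one(x, train=train, rng=rng) for x in batch]

    def backward(self, d_rates: np.ndarray) -> np.ndarray:
        dy = self.softplus.backward(np.asarray(d_rates, dtype=nn.DTYPE))
        dy = self.head.backward(dy)
        # With a fully frozen trunk only the head gradient is needed, so
        # the (dominant) trunk backward pass can be skipped entirely.
        if all(not p.trainable for p in self.trunk.parameters()):
            return dy
        return self.trunk.backward(dy)

    # -- head / freezing manipulation ------------------------------------
    @property
    def head_in_width(self) -> int:
        return self.head.c_in

    def replace_head(self, new_num_tracks: int, seed: int) -> "Model":
        """Swap in a freshly initialized head for ``new_num_tracks`` tracks;
        trunk parameters are untouched (in place; returns self)."""
        if new_num_tracks < 1:
            raise ConfigurationError("new_num_tracks must be >= 1")
        rng = np.random.default_rng(seed)
        self.head = Linear("head", self.head_in_width, new_num_tracks, rng,
                           group="head")
        self.config = dataclasses.replace(self.config, num_tracks=new_num_tracks)
        return self

    def set_frozen(self, freeze_trunk: bool) -> "Model":
        for p in self.trunk.parameters():
            p.trainable = not freeze_trunk
        return self


def build_model(config: ArchitectureConfig, seed: int) -> Model:
    """Construct and initialize a model; all randomness comes from ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    widths = _tower_widths(config)
    mods: List[Module] = []

    # Stem: plain conv on one-hot input, then pooling stage 1.
    mods.append(Conv1d("stem.conv", 4, widths[0], config.stem_kernel_size, rng))
    pools_left = config.num_pooling_stages
    if pools_left > 0:
        mods.append(_make_pool("stem.pool", config, widths[0]))
        pools_left -= 1

    # Tower: pre-norm conv blocks, residual when the width is unchanged.
    for i in range(1, config.num_conv_blocks):
        cin, cout = widths[i - 1], widths[i]
        body = Sequential([
            LayerNorm(f"tower{i}.ln", cin),
            GELU(),
            Conv1d(f"tower{i}.conv", cin, cout, config.conv_kernel_size, rng),
        ])
        mods.append(Residual(body) if cin == cout else body)
        if pools_left > 0:
            mods.append(_make_pool(f"tower{i}.pool", config, cout))
            pools_left -= 1

    # Attention stack over one position per bin.
    n_pos = config.total_bins
    use_out_proj = config.use_attention_linear or config.attention_linear_site != "output_projection"
    for i in range(config.num_attention_blocks):
        attn = Sequential([
            LayerNorm(f"attn{i}.ln", config.model_width),
            MultiHeadAttention(
                f"attn{i}.mha", config.model_width, config.num_heads,
                config.head_dim, n_pos, config.positional_scheme,
                use_out_proj, rng,
            ),
            Dropout(config.dropout_rate),
        ])
        mods.append(Residual(attn))
        mods.append(Residual(_ffn(f"attn{i}.ffn", config, rng)))

    mods.append(CenterCrop(config.output_bins))

    head_in = config.model_width
    if config.use_final_pointwise:
        mods.append(LayerNorm("pointwise.ln", config.model_width))
        mods.append(Linear("pointwise.lin", config.model_width,
                           2 * config.model_width, rng))
        mods.append(GELU())
        mods.append(Dropout(config.dropout_rate))
        head_in = 2 * config.model_width

    head = Linear("head", head_in, config.num_tracks, rng, group="head")
    return Model(config, Sequential(mods), head, Softplus())


def count_parameters(model: Model, group: str = "all") -> int:
    """Exact number of scalar parameters in ``group`` ('all'/'trunk'/'head')."""
    return sum(p.size for p in model.parameters(group))


def param_checksum(model: Model, group: str = "all") -> float:
    """Order-independent fingerprint of parameter values, for change audits."""
    return float(sum(np.abs(p.value).sum() + p.value.sum() * 0.5
                     for p in model.parameters(group)))
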