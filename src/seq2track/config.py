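"""Architecture and training configuration.

``ArchitectureConfig`` captures every structural knob of the network:
resolution arithmetic (input length, bin size, pooling depth, output
cropping), block counts, attention geometry, and the two ablation flags —
the final pointwise convolution and the "extra" linear layer inside each
attention block — whose removal defines the simplified variant this
package adopts by default.

``TrainingConfig`` captures the training protocol: AdamW with a linear
warmup/decay learning-rate schedule, Poisson-NLL objective in multi-track
or single-track mode, batch size 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

ATTENTION_LINEAR_SITES = ("output_projection", "ffn_second")
POSITIONAL_SCHEMES = ("relative_bias", "learned_relative", "none")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural description of a sequence-to-track model.

    Defaults describe the full-scale network: a 196,608-bp input, seven
    pooling stages (2^7 = 128-bp bins), seven convolutional blocks, eleven
    attention blocks, and an 896-bin cropped output. The adopted simplified
    variant omits both the final pointwise convolution and the attention
    output projection (``use_final_pointwise=False``,
    ``use_attention_linear=False``).
    """

    sequence_length: int = 196_608
    bin_size: int = 128
    num_pooling_stages: int = 7
    num_conv_blocks: int = 7
    num_attention_blocks: int = 11
    model_width: int = 96
    num_heads: int = 8
    head_dim: int = 12
    use_attention_linear: bool = False
    attention_linear_site: str = "output_projection"
    use_final_pointwise: bool = False
    output_bins: int = 896
    num_tracks: int = 1
    positional_scheme: str = "relative_bias"
    dropout_rate: float = 0.0
    output_nonlinearity: str = "softplus"
    conv_kernel_size: int = 5
    stem_kernel_size: int = 15
    pooling_type: str = "attention"  # or "max"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def total_bins(self) -> int:
        return self.sequence_length // self.bin_size

    @property
    def crop_per_side(self) -> int:
        return (self.total_bins - self.output_bins) // 2

    def validate(self) -> None:
        c = self
        if 2 ** c.num_pooling_stages != c.bin_size:
            raise ConfigurationError(
                f"2^num_pooling_stages must equal bin_size: "
                f"2^{c.num_pooling_stages}={2 ** c.num_pooling_stages} != {c.bin_size}"
            )
        if c.sequence_length % c.bin_size != 0:
            raise ConfigurationError(
                f"sequence_length {c.sequence_length} not divisible by "
                f"bin_size {c.bin_size}"
            )
        margin = c.total_bins - c.output_bins
        if margin < 0 or margin % 2 != 0:
            raise ConfigurationError(
                f"crop_per_side = (sequence_length/bin_size - output_bins)/2 "
                f"= ({c.total_bins} - {c.output_bins})/2 must be a "
                f"non-negative integer"
            )
        if c.num_conv_blocks < c.num_pooling_stages:
            raise ConfigurationError(
                f"num_conv_blocks ({c.num_conv_blocks}) must be >= "
                f"num_pooling_stages ({c.num_pooling_stages}); every pooling "
                f"stage is attached to a convolutional block"
            )
        if c.num_conv_blocks < 1 or c.num_attention_blocks < 0:
            raise ConfigurationError("block counts must be positive")
        if c.attention_linear_site not in ATTENTION_LINEAR_SITES:
            raise ConfigurationError(
                f"attention_linear_site must be one of {ATTENTION_LINEAR_SITES}"
            )
        if c.positional_scheme not in POSITIONAL_SCHEMES:
            raise ConfigurationError(
                f"positional_scheme must be one of {POSITIONAL_SCHEMES}"
            )
        if c.pooling_type not in ("attention", "max"):
            raise ConfigurationError("pooling_type must be 'attention' or 'max'")
        if c.output_nonlinearity != "softplus":
            raise ConfigurationError("output_nonlinearity must be 'softplus'")
        # Without an output projection the concatenated heads feed the
        # residual stream directly, so their total width must match it.
        if (
            not c.use_attention_linear
            and c.attention_linear_site == "output_projection"
            and c.num_heads * c.head_dim != c.model_width
        ):
            raise ConfigurationError(
                f"num_heads*head_dim ({c.num_heads}*{c.head_dim}="
                f"{c.num_heads * c.head_dim}) must equal model_width "
                f"({c.model_width}) when the attention output projection "
                f"is removed"
            )
        if c.num_tracks < 1:
            raise ConfigurationError("num_tracks must be >= 1")
        if not 0.0 <= c.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureConfig":
        return cls.from_dict(json.loads(s))

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "ArchitectureConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol: 10 epochs of AdamW at batch size 1 with a linear
    warmup over the first epoch and linear decay to zero over the rest."""

    epochs: int = 10
    peak_lr: float = 3e-5
    weight_decay: float = 1e-4
    warmup_epochs: int = 1
    batch_size: int = 1
    mode: str = "multi_track"
    track_index: Optional[int] = None
    shuffle_seed: int = 0
    grad_clip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("multi_track", "single_track"):
            raise ConfigurationError("mode must be multi_track or single_track")
        if self.mode == "single_track" and self.track_index is None:
            raise ConfigurationError("single_track mode requires track_index")
        if self.peak_lr <= 0:
            raise ConfigurationError("peak_lr must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0, batch_size >= 1")
        if self.epochs > 0 and not 0 <= self.warmup_epochs < self.epochs:
            raise ConfigurationError(
                f"warmup_epochs ({self.warmup_epochs}) must be in "
                f"[0, epochs={self.epochs})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "TrainingConfig":
        return dataclasses.replace(self, **kw)
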