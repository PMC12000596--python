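"""Run and network configuration, serializable to YAML losslessly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class NetworkConfig:
    """Hyperparameters of the attention-based CNN-BiGRU regressor.

    Defaults: three 1D conv layers with
    64/32/16 kernels of size 2, a 16-unit dense bottleneck, two stacked
    bidirectional GRU layers, Adam at learning rate 0.01, mean-absolute-error
    loss, 95 epochs.
    """

    conv_filters: tuple = (64, 32, 16)
    kernel_size: int = 2
    #: pad the first conv layer to keep sequence length (5 -> 5 -> 4 -> 3);
    #: without it three valid kernel-2 layers would leave only 2 positions
    conv_same_pad_first: bool = True
    bottleneck_units: int = 16
    gru_layers: int = 2
    gru_hidden: int = 64
    learning_rate: float = 0.01
    #: per-epoch multiplicative decay of the (initial) learning rate; MAE
    #: gradients do not vanish near the optimum, so a decaying step is needed
    #: for the loss to settle rather than jitter
    lr_decay: float = 0.93
    #: global gradient-norm clip (None disables); guards the recurrent stack
    #: against occasional exploding updates
    grad_clip_norm: float | None = 1.0
    epochs: int = 95
    loss: str = "mae"
    batch_size: int = 32
    seed: int = 0
    input_channels: int = 24
    sequence_length: int = 5
    #: ablation flags
    no_cnn: bool = False
    drop_one_gru_layer: bool = False
    no_attention: bool = False
    #: combine bidirectional states by learned per-feature weights (default)
    #: or by concatenation
    bigru_combine: str = "weighted"

    def __post_init__(self):
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        if any(f <= 0 for f in self.conv_filters):
            raise ValueError("conv_filters must be positive")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.bottleneck_units, self.gru_hidden, self.gru_layers,
               self.batch_size, self.input_channels, self.sequence_length) <= 0:
            raise ValueError("all sizes must be positive")
        if self.bigru_combine not in ("weighted", "concat"):
            raise ValueError("bigru_combine must be 'weighted' or 'concat'")
        if self.drop_one_gru_layer and self.gru_layers < 2:
            raise ValueError("cannot drop a GRU layer from a single-layer stack")


@dataclass
class RunConfig:
    """Top-level configuration for a command-line run."""

    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    split_strategy: str = "holdout_year"
    test_year: int = 2021
    val_fraction: float = 0.2
    in_season_stage: int = 5
    panel_path: str = "panel.csv"
    output_dir: str = "runs"
    normalization: str = "zscore"
    outlier_k: float = 4.0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["network"]["conv_filters"] = list(self.network.conv_filters)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        net = d.pop("network", {})
        known = {f.name for f in fields(cls)} - {"network"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(network=NetworkConfig(**net), **d)
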