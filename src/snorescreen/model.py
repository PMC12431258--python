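"""ERBG-Net: ECA-augmented ResNet backbone with a BiGRU temporal head.

The classifier consumes single-channel 128x128 log-Mel spectrograms.  A
ResNet18 (or ResNet34) backbone extracts spatial features; efficient
channel attention (ECA) modules after the second convolution of each
residual block in the conv4_x/conv5_x stages recalibrate channel
responses; the final feature map is unfolded along its width (the time
axis of the spectrogram) into a sequence of (channels x height) vectors
which a bidirectional GRU summarizes.  The concatenated last forward and
backward hidden states feed a single linear layer producing class logits.

Ablation variants (plain ResNet18, ResNet18+BiGRU, ECA-ResNet18,
ECA-ResNet34+BiGRU) are reachable purely through :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .nn import (
    BatchNorm2d,
    BiGRU,
    Conv2d,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    Parameter,
    ReLU,
    Sequential,
    Tensor,
    conv1d_channels,
)

__all__ = [
    "EcaConfig",
    "ModelConfig",
    "BiGruParams",
    "eca_kernel_size",
    "eca_forward",
    "bigru_forward",
    "build_model",
    "TABLE_VARIANTS",
]

_STAGES = ("conv2_x", "conv3_x", "conv4_x", "conv5_x")
_BLOCKS = {"resnet18": (2, 2, 2, 2), "resnet34": (3, 4, 6, 3)}
_CHANNELS = (64, 128, 256, 512)


@dataclass(frozen=True)
class EcaConfig:
    """ECA kernel-size hyperparameters (gamma, b)."""

    gamma: float = 2.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "resnet18"
    eca_stages: frozenset = frozenset({"conv4_x", "conv5_x"})
    use_bigru: bool = True
    bigru_hidden: int = 128
    bigru_layers: int = 1
    n_classes: int = 2
    input_shape: tuple[int, int, int] = (1, 128, 128)
    eca: EcaConfig = field(default_factory=EcaConfig)

    def __post_init__(self) -> None:
        if self.backbone not in _BLOCKS:
            raise ValidationError(f"unknown backbone {self.backbone!r}")
        stages = frozenset(self.eca_stages)
        if not stages <= set(_STAGES):
            raise ValidationError(f"eca_stages must be within {_STAGES}")
        object.__setattr__(self, "eca_stages", stages)
        if self.bigru_hidden < 1 or self.bigru_layers < 1:
            raise ValidationError("BiGRU width/depth must be positive")
        if self.bigru_layers != 1:
            raise ValidationError("only single-layer BiGRU is implemented")


#: The ablation-table architectures, all expressed as configurations.
TABLE_VARIANTS: dict[str, ModelConfig] = {
    "resnet18": ModelConfig(eca_stages=frozenset(), use_bigru=False),
    "resnet18_bigru": ModelConfig(eca_stages=frozenset(), use_bigru=True),
    "eca_resnet18": ModelConfig(use_bigru=False),
    "eca_resnet34_bigru": ModelConfig(backbone="resnet34"),
    "erbg_net": ModelConfig(),
}


def eca_kernel_size(n_channels: int, eca: EcaConfig | None = None) -> int:
    """Adaptive odd 1-D kernel width: k = |log2(C)/gamma + b| rounded odd.

    The raw value is rounded to the nearest integer (ties to even, numpy
    convention) and bumped to the next odd integer if even; floor at 1.
    """
    if n_channels < 1:
        raise ValidationError("channel count must be >= 1")
    eca = eca or EcaConfig()
    t = int(np.rint(np.log2(n_channels) / eca.gamma + eca.b))
    if t % 2 == 0:
        t += 1
    return max(t, 1)


def eca_forward(feature_map: np.ndarray | Tensor, k: int,
                weight: np.ndarray | Tensor | None = None) -> Tensor:
    """Functional ECA: GAP over space, k-wide 1-D conv across channels,
    sigmoid, channel-wise rescale.  Accepts (C, H, W) or (B, C, H, W)."""
    if k % 2 == 0 or k < 1:
        raise ValidationError("ECA kernel width must be odd and >= 1")
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(
        np.asarray(feature_map, dtype=np.float64)
    )
    squeeze = x.data.ndim == 3
    if squeeze:
        x = x.reshape((1,) + x.data.shape)
    if weight is None:
        weight = np.zeros(k)
    w = weight if isinstance(weight, Tensor) else Tensor(np.asarray(weight, float))
    y = x.mean(axis=3).mean(axis=2)  # (B, C) global average pooling
    att = conv1d_channels(y, w).sigmoid()
    out = x * att.reshape(att.data.shape + (1, 1))
    return out.reshape(out.data.shape[1:]) if squeeze else out


class EcaModule(Module):
    def __init__(self, n_channels: int, eca: EcaConfig):
        super().__init__()
        self.k = eca_kernel_size(n_channels, eca)
        self.weight = Parameter(np.zeros(self.k))  # sigma(0)=0.5 at init

    def forward(self, x: Tensor) -> Tensor:
        y = x.mean(axis=3).mean(axis=2)
        att = conv1d_channels(y, self.weight).sigmoid()
        return x * att.reshape(att.data.shape + (1, 1))


class BasicBlock(Module):
    """Standard two-conv residual block, optionally with ECA applied after
    the second convolution's batch norm, before the residual addition."""

    def __init__(self, c_in, c_out, stride, use_eca, eca_cfg, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.eca = EcaModule(c_out, eca_cfg) if use_eca else None
        if stride != 1 or c_in != c_out:
            self.down_conv = Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            self.down_bn = BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        if self.eca is not None:
            out = self.eca(out)
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + shortcut).relu()


class ErbgNet(Module):
    """The configurable classifier; see module docstring."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c_in = config.input_shape[0]
        self.stem = Sequential(
            Conv2d(c_in, 64, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        stages = []
        prev = 64
        for stage_name, c_out, n_blocks in zip(
            _STAGES, _CHANNELS, _BLOCKS[config.backbone]
        ):
            use_eca = stage_name in config.eca_stages
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage_name != "conv2_x") else 1
                blocks.append(
                    BasicBlock(prev, c_out, stride, use_eca, config.eca, rng)
                )
                prev = c_out
            stages.append(Sequential(*blocks))
        self.stages = stages

        if config.use_bigru:
            # final map (B, C, H', W') unfolds along W' (time) into
            # sequences of C*H'-dim vectors
            h_out = config.input_shape[1] // 32
            self.bigru = BiGRU(_CHANNELS[-1] * h_out, config.bigru_hidden, rng)
            self.head = Linear(2 * config.bigru_hidden, config.n_classes, rng)
            self.gap = None
        else:
            self.bigru = None
            self.gap = GlobalAvgPool2d()
            self.head = Linear(_CHANNELS[-1], config.n_classes, rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:
            x = x.reshape((1,) + x.data.shape)
        if x.data.shape[1:] != self.config.input_shape:
            raise ValidationError(
                f"input shape {x.data.shape[1:]} != {self.config.input_shape}"
            )
        out = self.stem(x)
        for stage in self.stages:
            out = stage(out)
        if self.bigru is not None:
            b, c, h, w = out.data.shape
            seq = out.transpose(0, 3, 1, 2).reshape(b, w, c * h)
            _, last = self.bigru(seq)
            return self.head(last)
        return self.head(self.gap(out))


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ErbgNet:
    """Construct an (untrained) model with seeded initialization."""
    config = config or ModelConfig()
    return ErbgNet(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Functional BiGRU with explicit parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiGruParams:
    """Explicit forward/backward GRU parameters.

    Each direction is a dict with keys wxz, wxr, wxc (d x h), whz, whr,
    whc (h x h) and bz, br, bc (h,).  Forward and backward shapes must
    match.
    """

    forward: dict
    backward: dict

    def __post_init__(self) -> None:
        for key in ("wxz", "wxr", "wxc", "whz", "whr", "whc", "bz", "br", "bc"):
            if key not in self.forward or key not in self.backward:
                raise ValidationError(f"missing GRU parameter {key!r}")
            if np.shape(self.forward[key]) != np.shape(self.backward[key]):
                raise ValidationError("forward/backward parameter shapes must match")

    @property
    def hidden(self) -> int:
        return np.shape(self.forward["bz"])[0]

    @staticmethod
    def random(d_in: int, hidden: int, rng: np.random.Generator) -> "BiGruParams":
        def direction():
            bound = 1.0 / np.sqrt(hidden)
            return {
                "wxz": rng.uniform(-bound, bound, (d_in, hidden)),
                "wxr": rng.uniform(-bound, bound, (d_in, hidden)),
                "wxc": rng.uniform(-bound, bound, (d_in, hidden)),
                "whz": rng.uniform(-bound, bound, (hidden, hidden)),
                "whr": rng.uniform(-bound, bound, (hidden, hidden)),
                "whc": rng.uniform(-bound, bound, (hidden, hidden)),
                "bz": rng.uniform(-bound, bound, hidden),
                "br": rng.uniform(-bound, bound, hidden),
                "bc": rng.uniform(-bound, bound, hidden),
            }

        return BiGruParams(direction(), direction())

    def swapped(self) -> "BiGruParams":
        return BiGruParams(self.backward, self.forward)


def _gru_direction_pass(xs: np.ndarray, p: dict) -> np.ndarray:
    """Run one GRU direction over (T, d) inputs; returns (T, h) states."""
    h = np.zeros(np.shape(p["bz"])[0])
    out = []
    for x_t in xs:
        z = 1.0 / (1.0 + np.exp(-(x_t @ p["wxz"] + h @ p["whz"] + p["bz"])))
        r = 1.0 / (1.0 + np.exp(-(x_t @ p["wxr"] + h @ p["whr"] + p["br"])))
        c = np.tanh(x_t @ p["wxc"] + r * (h @ p["whc"]) + p["bc"])
        h = (1.0 - z) * h + z * c
        out.append(h)
    return np.array(out)


def bigru_forward(sequence: np.ndarray, params: BiGruParams) -> np.ndarray:
    """Bidirectional GRU over a (T, d) sequence -> (T, 2h) hidden states.

    The forward direction runs t = 1..T, the backward direction t = T..1;
    per-step states are concatenated [h_fwd ; h_bwd].
    """
    xs = np.atleast_2d(np.asarray(sequence, dtype=np.float64))
    if xs.shape[0] < 1:
        raise ValidationError("sequence must contain at least one step")
    hf = _gru_direction_pass(xs, params.forward)
    hb = _gru_direction_pass(xs[::-1], params.backward)[::-1]
    return np.concatenate([hf, hb], axis=1)
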