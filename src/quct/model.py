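"""Multi-encoder signal-to-image network for quantized-SoS inversion.

The network maps a multistatic measurement tensor (n_tx, T, n_rx) to a
per-pixel class-probability map (C, H, W).  Each transmitter's record is
processed independently by a *shared-weight* input network (encoder over
the time x receiver plane, decoder of two transposed convolutions up to
the image size); the n_tx feature maps are concatenated channel-wise and
fused by an output network, a three-level UNet++-style nested grid with a
x3 down/upsampling factor.

Three variants are provided:

* ``large`` — encoder stages 1-3 are Shift Units (multi-kernel dilated
  residual blocks with strided shape-shifting paths); processing blocks
  come in pairs;
* ``base``  — each Shift Unit is replaced by a single strided convolution;
* ``small`` — additionally every paired processing block becomes single.

Free layer widths (the per-stage channel counts below) were calibrated so
that the three variants realize their published trainable-parameter
budgets exactly; the architecture is otherwise fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .phantoms import QuantizationScheme, labels_to_sos

__all__ = [
    "BlockSpec", "SUStageConfig", "ShiftUnitConfig", "EncoderStageConfig",
    "InputNetConfig", "OutputNetConfig", "ModelConfig", "NetworkSummary",
    "ConvNeXtBlock", "ShiftUnit", "InputNetwork", "OutputNetwork",
    "SignalToImageNet", "build_model", "full_config", "tiny_config",
    "count_trainable_params", "summarize", "predict",
]


@dataclass(frozen=True)
class BlockSpec:
    """Kernel size, filter count, stride and dilation of one block."""
    k: int
    f: int
    s: int = 1
    d: int = 1

    def __post_init__(self):
        if min(self.k, self.f, self.s, self.d) < 1:
            raise ValueError("BlockSpec fields must all be >= 1")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvNeXtBlock(nn.Module):
    """Residual block: spatial conv -> LN -> 1x1 expand x4 -> SELU -> 1x1
    project -> add input.

    ``depthwise=True`` gives the standard ConvNeXt form; with
    ``depthwise=False`` the spatial convolution is a full (optionally
    dilated) 2D convolution, the form used inside Shift Units.
    """

    def __init__(self, channels: int, kernel=7, dilation=1, depthwise=True,
                 rng=None):
        self.conv = nn.Conv2d(channels, channels, kernel, dilation=dilation,
                              padding="same", depthwise=depthwise, rng=rng)
        self.norm = nn.LayerNorm(channels)
        self.expand = nn.Conv2d(channels, 4 * channels, 1, rng=rng)
        self.project = nn.Conv2d(4 * channels, channels, 1, rng=rng)

    def forward(self, x):
        y = self.project(nn.selu(self.expand(self.norm(self.conv(x)))))
        return x + y


class BlockStack(nn.Module):
    """One or two sequential ConvNeXt blocks at the same width."""

    def __init__(self, channels, n_blocks, kernel=7, rng=None):
        self.blocks = [ConvNeXtBlock(channels, kernel, rng=rng)
                       for _ in range(n_blocks)]

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


@dataclass(frozen=True)
class SUStageConfig:
    """One shape-shifting stage of a Shift Unit (three parallel paths)."""
    kernels: tuple[int, int, int]
    dilation: int
    stride: tuple[int, int]
    shift_kernel: int
    path_width: int            # channels of each parallel shifted path
    skip_width: int            # channels of the strided skip
    se_hidden: int

    @property
    def out_channels(self) -> int:
        return 3 * self.path_width + self.skip_width


@dataclass(frozen=True)
class ShiftUnitConfig:
    stage_a: SUStageConfig
    stage_b: SUStageConfig
    kernel_c: int              # stage-3 kernel (new field of view, no reshape)
    align_width: int           # 1x1 strided conv aligning stage-1 output
    merge_se_hidden: int


class SUStage(nn.Module):
    """Three parallel dilated residual blocks, each followed by a strided
    shape-shift convolution, concatenated with a strided skip of the input."""

    def __init__(self, c_in: int, cfg: SUStageConfig, rng=None):
        self.blocks = [ConvNeXtBlock(c_in, k, cfg.dilation, depthwise=False,
                                     rng=rng) for k in cfg.kernels]
        self.shifts = [nn.Conv2d(c_in, cfg.path_width, cfg.shift_kernel,
                                 stride=cfg.stride, padding="same", rng=rng)
                       for _ in cfg.kernels]
        self.skip = nn.Conv2d(c_in, cfg.skip_width, cfg.shift_kernel,
                              stride=cfg.stride, padding="same", rng=rng)
        self.se = nn.SEBlock(cfg.out_channels, cfg.se_hidden, rng=rng)

    def forward(self, x):
        paths = [shift(block(x)) for block, shift in zip(self.blocks, self.shifts)]
        return self.se(nn.concat(paths + [self.skip(x)], axis=1))


class ShiftUnit(nn.Module):
    """Three-stage multi-kernel reshaping unit.

    Stages 1-2 shape-shift; stage 3 processes at constant shape with a new
    kernel.  The three per-stage outputs are fused (the stage-1 output is
    aligned by a strided 1x1 convolution) into ``c_out`` channels.
    """

    def __init__(self, c_in: int, c_out: int, cfg: ShiftUnitConfig, rng=None):
        self.cfg = cfg
        self.stage_a = SUStage(c_in, cfg.stage_a, rng)
        ca = cfg.stage_a.out_channels
        self.stage_b = SUStage(ca, cfg.stage_b, rng)
        cb = cfg.stage_b.out_channels
        self.block_c = ConvNeXtBlock(cb, cfg.kernel_c, depthwise=False, rng=rng)
        self.align = nn.Conv2d(ca, cfg.align_width, 1, stride=cfg.stage_b.stride,
                               padding="same", rng=rng)
        self.merge = nn.Conv2d(cfg.align_width + 2 * cb, c_out, 1, rng=rng)
        self.merge_se = nn.SEBlock(c_out, cfg.merge_se_hidden, rng=rng)

    def forward_stages(self, x):
        a = self.stage_a(x)
        b = self.stage_b(a)
        c = self.block_c(b)
        return a, b, c

    def forward(self, x):
        a, b, c = self.forward_stages(x)
        fused = nn.concat([self.align(a), b, c], axis=1)
        return self.merge_se(self.merge(fused))


# ---------------------------------------------------------------------------
# input / output networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderStageConfig:
    out_channels: int
    strides: tuple[tuple[int, int], tuple[int, int]]
    conv_kernel: int                       # replacement conv (base/small)
    su: ShiftUnitConfig | None = None      # shift unit (large)

    @property
    def total_stride(self) -> tuple[int, int]:
        (a, b), (c, d) = self.strides
        return (a * c, b * d)


@dataclass(frozen=True)
class InputNetConfig:
    in_hw: tuple[int, int]                 # (time samples, receivers)
    stem_kernel: tuple[int, int]
    stem_channels: int
    stages: tuple[EncoderStageConfig, EncoderStageConfig, EncoderStageConfig]
    valid_kernels: tuple[tuple[int, int], tuple[int, int]]
    valid_channels: tuple[int, int]
    deconv_channels: tuple[int, int]       # (mid, out) widths of the decoder
    deconv_kernel: int = 3
    deconv_stride: int = 3
    block_kernel: int = 7                  # depthwise kernel of paired blocks
    stem_stride: tuple[int, int] = (1, 1)


class InputNetwork(nn.Module):
    """Shared per-transmitter encoder-decoder.

    Encoder: 3 shape-shifting stages (Shift Units or single convolutions)
    then 2 unpadded convolutions; decoder: 2 transposed convolutions that
    reach the output image size exactly.  One parameter set serves all
    transmitters.
    """

    def __init__(self, cfg: InputNetConfig, out_hw: int, use_su: bool,
                 n_blocks: int, rng=None):
        self.cfg = cfg
        hw = cfg.in_hw
        self.stem = nn.Conv2d(1, cfg.stem_channels, cfg.stem_kernel,
                              stride=cfg.stem_stride, padding="same", rng=rng)
        hw = (-(-hw[0] // cfg.stem_stride[0]), -(-hw[1] // cfg.stem_stride[1]))
        c_prev = cfg.stem_channels
        self.encoder_stages = []
        for i, st in enumerate(cfg.stages):
            if use_su:
                if st.su is None:
                    raise ValueError(f"stage {i + 1} lacks a Shift Unit config")
                if (st.su.stage_a.stride, st.su.stage_b.stride) != st.strides:
                    raise ValueError(f"stage {i + 1}: SU strides disagree with "
                                     "the stage stride contract")
                mod = ShiftUnit(c_prev, st.out_channels, st.su, rng)
            else:
                mod = nn.Conv2d(c_prev, st.out_channels, st.conv_kernel,
                                stride=st.total_stride, padding="same", rng=rng)
            self.encoder_stages.append(mod)
            sh, sw = st.total_stride
            hw2 = (-(-hw[0] // sh), -(-hw[1] // sw))
            if use_su:
                (s1h, s1w), (s2h, s2w) = st.strides
                mid = (-(-hw[0] // s1h), -(-hw[1] // s1w))
                if (-(-mid[0] // s2h), -(-mid[1] // s2w)) != hw2:
                    raise ValueError(
                        f"stage {i + 1}: composed stage strides are not "
                        f"equivalent to the single-stride path at input {hw}")
            hw = hw2
            c_prev = st.out_channels

        self.valid_convs = []
        self.valid_blocks = []
        for k, c_out in zip(cfg.valid_kernels, cfg.valid_channels):
            self.valid_convs.append(nn.Conv2d(c_prev, c_out, k, padding="valid",
                                              rng=rng))
            hw = nn.conv_out_shape(hw, k, 1, 1, "valid")
            self.valid_blocks.append(BlockStack(c_out, n_blocks,
                                                cfg.block_kernel, rng))
            c_prev = c_out

        self.deconvs = []
        self.deconv_blocks = []
        for c_out in cfg.deconv_channels:
            self.deconvs.append(nn.ConvTranspose2d(c_prev, c_out,
                                                   cfg.deconv_kernel,
                                                   cfg.deconv_stride, rng=rng))
            hw = nn.conv_transpose_out_shape(hw, cfg.deconv_kernel,
                                             cfg.deconv_stride)
            self.deconv_blocks.append(BlockStack(c_out, n_blocks,
                                                 cfg.block_kernel, rng))
            c_prev = c_out
        if hw != (out_hw, out_hw):
            raise ValueError(f"decoder reaches {hw}, expected "
                             f"({out_hw}, {out_hw}); adjust stage strides or "
                             "kernels")
        self.out_channels = c_prev

    def forward(self, x):
        x = self.stem(x)
        for stage in self.encoder_stages:
            x = stage(x)
        for conv, blocks in zip(self.valid_convs, self.valid_blocks):
            x = blocks(conv(x))
        for deconv, blocks in zip(self.deconvs, self.deconv_blocks):
            x = blocks(deconv(x))
        return x


@dataclass(frozen=True)
class OutputNetConfig:
    width: int                         # level-0 filter count f (levels f, 3f, 9f)
    se_hidden_stem: int
    se_hidden_nodes: tuple[int, int, int]  # SE widths at the three merge nodes
    scale: int = 3
    block_kernel: int = 7


class OutputNetwork(nn.Module):
    """Three-level nested-skip (UNet++-style) fusion decoder.

    Levels use a x3 spatial scale and widths (f, 3f, 9f).  Merge nodes
    concatenate all same-level predecessors with the upsampled deeper node,
    recalibrate with an SE block, project back to the level width, and
    process with ConvNeXt blocks.  A 1x1 head plus softmax yields class
    probabilities.
    """

    def __init__(self, c_in: int, n_classes: int, out_hw: int,
                 cfg: OutputNetConfig, n_blocks: int, rng=None):
        f, s = cfg.width, cfg.scale
        if out_hw % s or (out_hw // s) % s:
            raise ValueError(f"output size {out_hw} is not twice divisible "
                             f"by the scale {s}")
        k = cfg.block_kernel
        self.stem = nn.Conv2d(c_in, f, 1, rng=rng)
        self.stem_se = nn.SEBlock(f, cfg.se_hidden_stem, rng=rng)
        self.node00 = BlockStack(f, n_blocks, k, rng)
        self.down1 = nn.Conv2d(f, 3 * f, s, stride=s, padding="same", rng=rng)
        self.node10 = BlockStack(3 * f, n_blocks, k, rng)
        self.down2 = nn.Conv2d(3 * f, 9 * f, s, stride=s, padding="same", rng=rng)
        self.node20 = BlockStack(9 * f, n_blocks, k, rng)
        self.up10 = nn.ConvTranspose2d(3 * f, f, s, s, rng=rng)
        self.se01 = nn.SEBlock(2 * f, cfg.se_hidden_nodes[0], rng=rng)
        self.proj01 = nn.Conv2d(2 * f, f, 1, rng=rng)
        self.node01 = BlockStack(f, n_blocks, k, rng)
        self.up20 = nn.ConvTranspose2d(9 * f, 3 * f, s, s, rng=rng)
        self.se11 = nn.SEBlock(6 * f, cfg.se_hidden_nodes[1], rng=rng)
        self.proj11 = nn.Conv2d(6 * f, 3 * f, 1, rng=rng)
        self.node11 = BlockStack(3 * f, n_blocks, k, rng)
        self.up11 = nn.ConvTranspose2d(3 * f, f, s, s, rng=rng)
        self.se02 = nn.SEBlock(3 * f, cfg.se_hidden_nodes[2], rng=rng)
        self.proj02 = nn.Conv2d(3 * f, f, 1, rng=rng)
        self.node02 = BlockStack(f, n_blocks, k, rng)
        self.head = nn.Conv2d(f, n_classes, 1, rng=rng)

    def forward(self, x):
        x00 = self.node00(self.stem_se(self.stem(x)))
        x10 = self.node10(self.down1(x00))
        x20 = self.node20(self.down2(x10))
        x01 = self.node01(self.proj01(self.se01(
            nn.concat([x00, self.up10(x10)], axis=1))))
        x11 = self.node11(self.proj11(self.se11(
            nn.concat([x10, self.up20(x20)], axis=1))))
        x02 = self.node02(self.proj02(self.se02(
            nn.concat([x00, x01, self.up11(x11)], axis=1))))
        return nn.softmax(self.head(x02), axis=1)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    variant: str = "large"
    n_sensors: int = 32
    in_time: int = 1001
    in_rx: int = 32
    out_hw: int = 153
    n_classes: int = 8
    input_net: InputNetConfig | None = None
    output_net: OutputNetConfig | None = None

    def __post_init__(self):
        if self.variant not in ("small", "base", "large"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


class SignalToImageNet(nn.Module):
    """Full model: shared input network over all transmitters, channel-wise
    concatenation of the per-transmitter feature maps, fusion output network."""

    def __init__(self, cfg: ModelConfig, rng=None):
        self.config = cfg
        use_su = cfg.variant == "large"
        n_blocks = 1 if cfg.variant == "small" else 2
        self.input_net = InputNetwork(cfg.input_net, cfg.out_hw, use_su,
                                      n_blocks, rng)
        c_cat = cfg.n_sensors * self.input_net.out_channels
        self.output_net = OutputNetwork(c_cat, cfg.n_classes, cfg.out_hw,
                                        cfg.output_net, n_blocks, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """x: (batch, n_tx, T, n_rx) or (n_tx, T, n_rx) -> (batch, C, H, W)."""
        cfg = self.config
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        b, n_tx, T, R = x.shape
        if (n_tx, T, R) != (cfg.n_sensors, cfg.in_time, cfg.in_rx):
            raise ValueError(f"measurement shape {(n_tx, T, R)} does not match "
                             f"model config {(cfg.n_sensors, cfg.in_time, cfg.in_rx)}")
        per_tx = x.reshape(b * n_tx, 1, T, R)
        feats = self.input_net(per_tx)             # (b*n_tx, f_out, H, W)
        f_out = self.input_net.out_channels
        fused = feats.reshape(b, n_tx * f_out, cfg.out_hw, cfg.out_hw)
        return self.output_net(fused)


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

def _su(kernels_a, kernels_b, kernel_c, dil, strides, shift_kernel,
        pa, ga, pb, gb, align, se_a, se_b, se_m):
    sa = SUStageConfig(kernels_a, dil, strides[0], shift_kernel, pa, ga, se_a)
    sb = SUStageConfig(kernels_b, dil, strides[1], shift_kernel, pb, gb, se_b)
    return ShiftUnitConfig(sa, sb, kernel_c, align, se_m)


def full_config(variant: str = "large") -> ModelConfig:
    """Default configuration: 32 sensors, 1001 time samples, 153x153 output,
    8 classes.

    Channel widths and SE bottleneck widths below are calibrated values:
    the published figures fix the topology but leave the per-stage filter
    counts under-determined, so the free widths were solved (integer
    search) to reproduce the published trainable-parameter budgets of all
    three variants exactly.
    """
    stages = (
        EncoderStageConfig(
            out_channels=64, strides=((4, 1), (3, 1)), conv_kernel=7,
            su=_su((3, 5, 7), (3, 5, 7), 9, 2, ((4, 1), (3, 1)), 3,
                   pa=8, ga=8, pb=8, gb=8, align=16, se_a=8, se_b=2, se_m=2)),
        EncoderStageConfig(
            out_channels=112, strides=((2, 1), (2, 1)), conv_kernel=7,
            su=_su((3, 5, 7), (3, 5, 7), 9, 2, ((2, 1), (2, 1)), 3,
                   pa=24, ga=24, pb=40, gb=24, align=32, se_a=3, se_b=4, se_m=2)),
        EncoderStageConfig(
            out_channels=368, strides=((1, 1), (1, 1)), conv_kernel=7,
            su=_su((3, 5, 7), (3, 5, 7), 9, 2, ((1, 1), (1, 1)), 3,
                   pa=32, ga=24, pb=32, gb=24, align=64, se_a=2, se_b=2, se_m=87)),
    )
    input_net = InputNetConfig(
        in_hw=(1001, 32), stem_kernel=(7, 3), stem_channels=16,
        stages=stages, valid_kernels=((3, 9), (3, 8)),
        valid_channels=(208, 245), deconv_channels=(79, 8))
    output_net = OutputNetConfig(width=58, se_hidden_stem=4,
                                 se_hidden_nodes=(30, 22, 55))
    return ModelConfig(variant=variant, input_net=input_net,
                       output_net=output_net)


def tiny_config(variant: str = "large", n_sensors: int = 8, in_time: int = 201,
                out_hw: int = 27, n_classes: int = 4) -> ModelConfig:
    """Desk-scale profile for tests and demos (same machinery, small shapes)."""
    stages = (
        EncoderStageConfig(
            out_channels=10, strides=((3, 1), (3, 1)), conv_kernel=5,
            su=_su((1, 2, 3), (1, 2, 3), 3, 2, ((3, 1), (3, 1)), 3,
                   pa=3, ga=3, pb=3, gb=3, align=6, se_a=2, se_b=2, se_m=2)),
        EncoderStageConfig(
            out_channels=14, strides=((2, 1), (2, 1)), conv_kernel=5,
            su=_su((1, 2, 3), (1, 2, 3), 3, 2, ((2, 1), (2, 1)), 3,
                   pa=4, ga=4, pb=4, gb=4, align=8, se_a=2, se_b=2, se_m=2)),
        EncoderStageConfig(
            out_channels=18, strides=((1, 1), (1, 1)), conv_kernel=5,
            su=_su((1, 2, 3), (1, 2, 3), 3, 2, ((1, 1), (1, 1)), 3,
                   pa=5, ga=3, pb=5, gb=3, align=8, se_a=2, se_b=2, se_m=2)),
    )
    input_net = InputNetConfig(
        in_hw=(in_time, n_sensors), stem_kernel=(5, 3), stem_channels=6,
        stem_stride=(2, 1), stages=stages, valid_kernels=((1, 4), (1, 3)),
        valid_channels=(20, 24), deconv_channels=(12, 4), block_kernel=5)
    output_net = OutputNetConfig(width=8, se_hidden_stem=2,
                                 se_hidden_nodes=(2, 3, 2), block_kernel=5)
    return ModelConfig(variant=variant, n_sensors=n_sensors, in_time=in_time,
                       in_rx=n_sensors, out_hw=out_hw, n_classes=n_classes,
                       input_net=input_net, output_net=output_net)


def build_model(cfg: ModelConfig, seed: int | None = 0) -> SignalToImageNet:
    """Build a model; ``seed=None`` allocates zero weights (fast, for
    architecture accounting), otherwise Kaiming-normal initialization."""
    rng = None if seed is None else np.random.default_rng(seed)
    return SignalToImageNet(cfg, rng)


# ---------------------------------------------------------------------------
# accounting and inference
# ---------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    layers: list = field(default_factory=list)   # (name, n_params)
    total_trainable: int = 0

    def as_dict(self):
        return {"layers": [{"name": n, "params": p} for n, p in self.layers],
                "total_trainable": self.total_trainable}


def count_trainable_params(model: nn.Module) -> int:
    """Independent trainable scalars; shared weights counted once."""
    return model.count_params()


def summarize(model: SignalToImageNet) -> NetworkSummary:
    summary = NetworkSummary()
    seen: set[int] = set()
    for name, p in model.named_parameters():
        if id(p) in seen:
            continue
        seen.add(id(p))
        summary.layers.append((name, int(p.data.size)))
    summary.total_trainable = sum(p for _, p in summary.layers)
    return summary


def predict(model: SignalToImageNet, measurement, scheme: QuantizationScheme):
    """Forward pass plus argmax decoding and SoS rendering.

    Returns (probability map, label map, SoS map); ties in the argmax go to
    the lowest class index.
    """
    data = measurement.data if hasattr(measurement, "data") else measurement
    arr = np.asarray(data, dtype=np.float32)
    with nn.no_grad():
        probs = model(nn.Tensor(arr)).data
    labels = probs.argmax(axis=1).astype(np.uint8)   # argmax -> lowest on ties
    sos = labels_to_sos(labels, scheme)
    if labels.shape[0] == 1:
        probs, labels, sos = probs[0], labels[0], sos[0]
    return probs, labels, sos
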