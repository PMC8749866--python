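"""First-stage dual-decoder U-Net and second-stage refiner.

The first-stage network (U-Net1) is a 3D U-Net variant with one shared image
encoder and two parallel decoders: the image decoder produces a rough
segmentation (2-class softmax) and the distance decoder regresses the
distance weight map.  The encoder is an initial convolutional layer followed
by three basic modules (convolution module + down-sampling); channels default
to 16, 32, 64, 128.  Every convolution module is two 3x3x3 convolutions with
group normalization and ReLU applied before each convolution.  Decoders
mirror the encoder with three basic modules each; at every level the
up-sampled feature map is concatenated with the same-resolution encoder
input before the convolution module.  The image decoder up-samples with
transposed convolutions, the distance decoder with (fixed) trilinear
interpolation.

The second-stage network (U-Net2) has the identical topology with the
distance decoder removed; its default input is the 2-channel concatenation
(segmentation probability, predicted distance map) of the first stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for callers wiring training loops)
    Conv3d,
    ConvTranspose3d,
    GroupNorm,
    Module,
    Tensor,
    concat,
    maxpool3d_2x,
    softmax,
    upsample_trilinear_2x,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the encoder/decoder topology."""

    in_channels: int = 1
    channel_widths: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 3
    norm_groups: int = 4
    with_distance_decoder: bool = True
    out_classes: int = 2
    down_mode: str = "stride"  # "stride" (strided conv) or "pool" (max pool)
    distance_activation: str = "sigmoid"  # or "linear" for unnormalised targets

    def __post_init__(self) -> None:
        widths = tuple(int(w) for w in self.channel_widths)
        object.__setattr__(self, "channel_widths", widths)
        if len(widths) < 2 or any(b <= a for a, b in zip(widths, widths[1:])):
            raise ValueError(
                f"channel_widths must be strictly increasing, length >= 2: {widths}"
            )
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if any(w % self.norm_groups for w in widths):
            raise ValueError(
                f"norm_groups={self.norm_groups} must divide every width {widths}"
            )
        if self.down_mode not in ("stride", "pool"):
            raise ValueError("down_mode must be 'stride' or 'pool'")
        if self.distance_activation not in ("sigmoid", "linear"):
            raise ValueError("distance_activation must be 'sigmoid' or 'linear'")

    @property
    def levels(self) -> int:
        """Number of down-sampling steps (spatial dims must divide 2**levels)."""
        return len(self.channel_widths) - 1


@dataclass
class StageOneOutput:
    """Outputs of the first stage on one crop (both spatially input-sized)."""

    segmentation: Tensor  # (N, 1, D, H, W) softmax foreground probability
    distance_pred: Tensor  # (N, 1, D, H, W)
    logits: Tensor | None = None


def _check_spatial(spec: NetworkSpec, spatial) -> None:
    div = 2**spec.levels
    bad = [s for s in spatial if s % div]
    if bad:
        raise ValueError(
            f"spatial dims {tuple(spatial)} must be divisible by {div} "
            f"for {spec.levels} down-sampling levels"
        )


class ConvModule(Module):
    """(GroupNorm -> ReLU -> Conv) x 2."""

    def __init__(self, in_ch, out_ch, spec: NetworkSpec, rng):
        g = spec.norm_groups
        self.norm1 = GroupNorm(g, in_ch)
        self.conv1 = Conv3d(in_ch, out_ch, spec.kernel_size, rng=rng)
        self.norm2 = GroupNorm(g, out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, spec.kernel_size, rng=rng)

    def forward(self, x):
        x = self.conv1(self.norm1(x).relu())
        return self.conv2(self.norm2(x).relu())


class Down(Module):
    """Down-sampling: strided 2x conv (default) or max pool + 1x1 conv."""

    def __init__(self, in_ch, out_ch, spec: NetworkSpec, rng):
        self.mode = spec.down_mode
        if self.mode == "stride":
            self.conv = Conv3d(in_ch, out_ch, spec.kernel_size, stride=2, rng=rng)
        else:
            self.conv = Conv3d(in_ch, out_ch, 1, rng=rng)

    def forward(self, x):
        if self.mode == "stride":
            return self.conv(x)
        return self.conv(maxpool3d_2x(x))


class Encoder(Module):
    def __init__(self, spec: NetworkSpec, rng):
        w = spec.channel_widths
        self.init_conv = Conv3d(spec.in_channels, w[0], spec.kernel_size, rng=rng)
        self.conv_modules = [
            ConvModule(w[i], w[i], spec, rng) for i in range(spec.levels)
        ]
        self.downs = [
            Down(w[i], w[i + 1], spec, rng) for i in range(spec.levels)
        ]

    def forward(self, x):
        """Return (bottleneck, skips); skips are each level's input feature map."""
        skips = []
        x = self.init_conv(x)
        for cm, down in zip(self.conv_modules, self.downs):
            skips.append(x)
            x = down(cm(x))
        return x, skips


class Decoder(Module):
    """Three basic modules; ``upsample`` is 'transposed' or 'trilinear'."""

    def __init__(self, spec: NetworkSpec, upsample: str, rng):
        w = spec.channel_widths
        self.upsample = upsample
        self.ups: list[Module | None] = []
        self.conv_modules = []
        for i in reversed(range(spec.levels)):
            top_ch = w[i + 1]
            if upsample == "transposed":
                self.ups.append(ConvTranspose3d(top_ch, w[i], rng=rng))
                in_ch = w[i] + w[i]  # upsampled + skip
            else:
                self.ups.append(None)  # fixed trilinear keeps channels
                in_ch = top_ch + w[i]
            self.conv_modules.append(ConvModule(in_ch, w[i], spec, rng))

    def forward(self, x, skips):
        for up, cm, skip in zip(self.ups, self.conv_modules, reversed(skips)):
            x = up(x) if up is not None else upsample_trilinear_2x(x)
            x = cm(concat([x, skip], axis=1))
        return x


class UNet(Module):
    """Shared-encoder U-Net with an image decoder and an optional parallel
    distance decoder."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.channel_widths
        self.encoder = Encoder(spec, rng)
        self.image_decoder = Decoder(spec, "transposed", rng)
        self.seg_head = Conv3d(w[0], spec.out_classes, 1, rng=rng)
        if spec.with_distance_decoder:
            self.distance_decoder = Decoder(spec, "trilinear", rng)
            self.dist_head = Conv3d(w[0], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> StageOneOutput:
        _check_spatial(self.spec, x.shape[2:])
        bottom, skips = self.encoder(x)
        logits = self.seg_head(self.image_decoder(bottom, skips))
        probs = softmax(logits, axis=1)
        seg = probs[:, 1:2]  # foreground channel
        if self.spec.with_distance_decoder:
            d = self.dist_head(self.distance_decoder(bottom, skips))
            if self.spec.distance_activation == "sigmoid":
                d = d.sigmoid()
        else:
            d = None
        return StageOneOutput(segmentation=seg, distance_pred=d, logits=logits)


def build_unet1(spec: NetworkSpec, seed: int = 0) -> UNet:
    """First-stage dual-decoder network; requires the distance decoder."""
    if not spec.with_distance_decoder:
        raise ValueError("U-Net1 requires with_distance_decoder=True")
    return UNet(spec, seed=seed)


def build_unet2(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Second-stage refiner: same topology, distance decoder removed."""
    if spec.with_distance_decoder:
        raise ValueError("U-Net2 must have with_distance_decoder=False")
    return UNet(spec, seed=seed)


def stage_bridge(stage1: StageOneOutput, image: Tensor | None = None) -> Tensor:
    """Channel concatenation (segmentation, distance) feeding stage 2.

    For the plain two-stage ablation (no distance decoder) the bridge is the
    segmentation probability alone.  Passing ``image`` appends the raw input
    volume as a trailing channel — the "automatic context" cascade variant
    in which the refiner also sees the original intensities.
    """
    channels = [stage1.segmentation]
    if stage1.distance_pred is not None:
        if stage1.segmentation.shape != stage1.distance_pred.shape:
            raise ValueError(
                f"stage-1 output shapes differ: {stage1.segmentation.shape} vs "
                f"{stage1.distance_pred.shape}"
            )
        channels.append(stage1.distance_pred)
    if image is not None:
        if image.shape != stage1.segmentation.shape:
            raise ValueError(
                f"image shape {image.shape} does not match stage-1 output "
                f"{stage1.segmentation.shape}"
            )
        channels.append(image)
    if len(channels) == 1:
        return channels[0]
    return concat(channels, axis=1)
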