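"""Encoder-decoder depth network with gated residual adaptation blocks.

Architecture
------------
A U-Net style network maps a single endoscopic RGB image to metric depth.
The encoder halves the spatial resolution at each of its levels; the
decoder mirrors it, upsampling with ICNR-initialized sub-pixel (pixel
shuffle) convolutions — at initialization each upsampling stage is exactly
nearest-neighbor interpolation of a learned convolution, which suppresses
the checkerboard artifacts of naive deconvolution.  During training the
decoder is supervised at four levels: depth heads produce maps at full,
1/2, 1/4 and 1/8 resolution (level l has side length input/2^(l-1)).
Depth heads end in a softplus, so predictions are non-negative and the
log-gradient loss is well defined.

Domain adaptation
-----------------
For transfer to a new image domain the trained encoder is duplicated:
F_S stays frozen as the reference; F_R receives one gated residual block
after each encoder level.  A block computes

    out = x + R(x) * tan(alpha),     alpha learnable, initialized 0,

so at the start of adversarial training F_R is exactly F_S (ReZero-style
gating: tan(0) = 0) and domain-specific corrections fade in smoothly as
the gates open.  |alpha| is clamped below pi/2 to stay clear of the tan
pole; tanh gating is available as a variant.  Only the block parameters
and the gate scalars are ever trainable in F_R.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetworkConfig", "MultiScalePrediction", "DepthNet", "Encoder", "Decoder",
    "GatedBlock", "GatedEncoder", "GatedEncoderPair",
    "build_depth_network", "forward_depth", "encoder_features",
    "insert_gated_blocks", "gated_block_forward",
    "save_checkpoint", "load_checkpoint",
]

ALPHA_LIMIT = math.pi / 2 - 1e-3


@dataclass(frozen=True)
class NetworkConfig:
    n_encoder_levels: int = 5
    base_channels: int = 32          # doubles per level
    channel_cap: int = 256
    decoder_levels_with_output: int = 4
    input_size: int = 256
    init_depth_mm: float = 25.0      # head bias -> plausible depth at step 0
    gate_fn: str = "tan"             # "tan" (as specified) or "tanh" ablation

    def __post_init__(self):
        if self.decoder_levels_with_output > self.n_encoder_levels - 1:
            raise ValueError(
                "decoder_levels_with_output must be <= n_encoder_levels - 1")
        if self.input_size % (1 << self.n_encoder_levels):
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^{self.n_encoder_levels}")
        if self.gate_fn not in ("tan", "tanh"):
            raise ValueError("gate_fn must be 'tan' or 'tanh'")

    def channels(self, level: int) -> int:
        """Channel width of encoder level `level` (1-based)."""
        return min(self.base_channels * (1 << (level - 1)), self.channel_cap)


@dataclass
class MultiScalePrediction:
    """Depth outputs D*_l at decoder levels l = 1..4 (l=1 is full size)."""
    levels: list[tuple[int, Tensor]]

    @property
    def full(self) -> Tensor:
        for l, t in self.levels:
            if l == 1:
                return t
        raise ValueError("no full-resolution output present")

    def as_arrays(self) -> dict[int, np.ndarray]:
        return {l: t.data for l, t in self.levels}


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class _ConvBNRelu(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class EncoderLevel(nn.Module):
    """Halves spatial size: strided conv + refining conv, both normalized."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.down = _ConvBNRelu(in_ch, out_ch, 2, rng)
        self.refine = _ConvBNRelu(out_ch, out_ch, 1, rng)

    def __call__(self, x):
        return self.refine(self.down(x))


class Encoder(nn.Module):
    """Level i output has side input/2^i and config.channels(i) channels."""

    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        self.config = config
        self.levels = []
        in_ch = 3
        for i in range(1, config.n_encoder_levels + 1):
            out_ch = config.channels(i)
            self.levels.append(EncoderLevel(in_ch, out_ch, rng))
            in_ch = out_ch

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        for level in self.levels:
            x = level(x)
            feats.append(x)
        return feats


class SubPixelUp(nn.Module):
    """Conv producing 4x channels + pixel shuffle; ICNR initialized.

    With ICNR the r^2 output channels feeding one shuffled output channel
    share identical kernels, so at initialization the stage's output equals
    nearest-neighbor upsampling of the base (stride-1) convolution.
    """

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch * 4, 3, stride=1, padding=1, rng=rng)
        self.out_ch = out_ch
        # ICNR: draw an (out_ch, in_ch, 3, 3) kernel, repeat each output
        # channel r^2 = 4 times consecutively (pixel_shuffle's layout)
        base = self.conv.weight.data[::4].copy()
        self.conv.weight.data = np.repeat(base, 4, axis=0)

    def base_weight(self) -> np.ndarray:
        """Stride-1 kernel whose NN-upsampling this stage matches at init."""
        return self.conv.weight.data[::4]

    def __call__(self, x):
        return nn.pixel_shuffle(self.conv(x), 2)


class DecoderStage(nn.Module):
    def __init__(self, in_ch, skip_ch, out_ch, rng):
        super().__init__()
        self.up = SubPixelUp(in_ch, out_ch, rng)
        self.fuse = _ConvBNRelu(out_ch + skip_ch, out_ch, 1, rng)

    def __call__(self, x, skip: Tensor | None):
        x = self.up(x)
        if skip is not None:
            x = nn.concat([x, skip], axis=1)
        return self.fuse(x)


class DepthHead(nn.Module):
    def __init__(self, in_ch, init_depth_mm, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, 1, 3, stride=1, padding=1, rng=rng)
        # softplus(b) ~= b for b >> 1: start near a plausible cavity depth
        self.conv.bias.data[:] = init_depth_mm

    def __call__(self, x):
        return self.conv(x).softplus()


def _stage_channels(config: NetworkConfig, m: int) -> int:
    """Feature width of the decoder stage whose output side is input/2^m."""
    return config.channels(m) if m >= 1 else config.base_channels


class Decoder(nn.Module):
    """Mirrors the encoder; emits depth at the last `n_outputs` stages.

    The stage whose output side is input/2^m takes its skip connection from
    encoder level m (same resolution); the full-resolution stage (m = 0)
    concatenates the input image instead, since the encoder keeps no
    full-resolution features.  Emitted level l corresponds to m = l - 1.
    """

    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        self.config = config
        L = config.n_encoder_levels
        self.stages = []
        self.heads = []
        in_ch = config.channels(L)
        for m in range(L - 1, -1, -1):  # output side input/2^m
            skip_ch = config.channels(m) if m >= 1 else 3
            out_ch = _stage_channels(config, m)
            self.stages.append(DecoderStage(in_ch, skip_ch, out_ch, rng))
            in_ch = out_ch
        for l in range(config.decoder_levels_with_output, 0, -1):
            self.heads.append(DepthHead(_stage_channels(config, l - 1),
                                        config.init_depth_mm, rng))

    def __call__(self, feats: list[Tensor], image: Tensor) -> MultiScalePrediction:
        L = self.config.n_encoder_levels
        x = feats[-1]
        outputs: list[tuple[int, Tensor]] = []
        n_out = self.config.decoder_levels_with_output
        head_iter = iter(self.heads)
        for idx, stage in enumerate(self.stages):
            m = L - 1 - idx
            skip = feats[m - 1] if m >= 1 else image
            x = stage(x, skip)
            level = m + 1  # map side = input/2^(level-1)
            if level <= n_out:
                outputs.append((level, next(head_iter)(x)))
        outputs.reverse()  # level 1 first
        return MultiScalePrediction(levels=outputs)


class DepthNet(nn.Module):
    def __init__(self, config: NetworkConfig, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(config, rng)

    def __call__(self, images: Tensor) -> MultiScalePrediction:
        feats = self.encoder.features(images)
        return self.decoder(feats, images)


# ---------------------------------------------------------------------------
# Gated residual blocks and the encoder pair
# ---------------------------------------------------------------------------

class GatedBlock(nn.Module):
    """Channel-preserving residual transform faded in by tan(alpha)."""

    def __init__(self, ch: int, rng, gate_fn: str = "tan"):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, stride=1, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(ch)
        self.alpha = nn.Parameter(0.0)
        self.gate_fn = gate_fn

    def residual(self, x: Tensor) -> Tensor:
        return self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))

    def gate(self) -> Tensor:
        return self.alpha.tan() if self.gate_fn == "tan" else self.alpha.tanh()

    def clamp_alpha(self) -> None:
        if self.gate_fn == "tan":
            self.alpha.data = np.clip(self.alpha.data, -ALPHA_LIMIT, ALPHA_LIMIT)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.conv1.weight.data.shape[1]:
            raise ValueError("gated block channel mismatch")
        return x + self.residual(x) * self.gate()


def gated_block_forward(block: GatedBlock, x: Tensor | np.ndarray) -> Tensor:
    """out = x + R(x) * tan(alpha); the block's functional interface."""
    return block(nn.as_tensor(x))


class GatedEncoder(nn.Module):
    """A frozen encoder copy with one trainable gated block per level."""

    def __init__(self, encoder: Encoder, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        cfg = encoder.config
        self.base = Encoder(cfg, np.random.default_rng(0))
        self.base.load_state_dict(encoder.state_dict())
        self.base.freeze()
        self.blocks = [GatedBlock(cfg.channels(i), rng, cfg.gate_fn)
                       for i in range(1, cfg.n_encoder_levels + 1)]
        for m in self.modules():
            if isinstance(m, nn.BatchNorm2d):
                m.stats_frozen = True

    def features(self, x: Tensor) -> list[Tensor]:
        feats = []
        for level, block in zip(self.base.levels, self.blocks):
            x = block(level(x))
            feats.append(x)
        return feats

    def alphas(self) -> list[float]:
        return [float(b.alpha.data) for b in self.blocks]

    def clamp_alphas(self) -> None:
        for b in self.blocks:
            b.clamp_alpha()

    def trainable_parameters(self) -> list[Tensor]:
        return [p for b in self.blocks for p in b.parameters() if p.requires_grad]


class GatedEncoderPair(nn.Module):
    """Frozen source encoder F_S plus its gated, adaptable copy F_R."""

    def __init__(self, f_s: Encoder, f_r: GatedEncoder):
        super().__init__()
        self.f_s = f_s
        self.f_r = f_r


def insert_gated_blocks(encoder: Encoder, seed: int) -> GatedEncoderPair:
    """Duplicate a trained encoder into (frozen F_S, gated F_R).

    All alpha gates start at 0, so F_R initially reproduces F_S exactly.
    Batch-normalization running statistics are frozen in both copies, and
    only the gated blocks (and their gates) are trainable in F_R.
    """
    f_s = Encoder(encoder.config, np.random.default_rng(0))
    f_s.load_state_dict(encoder.state_dict())
    f_s.freeze()
    for m in f_s.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.stats_frozen = True
    f_r = GatedEncoder(encoder, seed)
    dt = encoder.param_dtype()
    f_s.to_dtype(dt)
    f_r.to_dtype(dt)
    pair = GatedEncoderPair(f_s, f_r)
    pair.eval()
    return pair


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def _to_nchw(images: np.ndarray | Tensor, dtype=None) -> Tensor:
    if isinstance(images, Tensor):
        return images
    arr = np.asarray(images, dtype=dtype or np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[-1] == 3:  # NHWC -> NCHW
        arr = arr.transpose(0, 3, 1, 2)
    return Tensor(arr)


def build_depth_network(config: NetworkConfig, seed: int) -> DepthNet:
    return DepthNet(config, seed)


def forward_depth(network: DepthNet, images) -> MultiScalePrediction:
    """Run the network; returns depth maps at 4 scales (level 1 = full)."""
    x = _to_nchw(images)
    size = network.config.input_size
    if x.data.shape[-2:] != (size, size):
        raise ValueError(f"expected {size}x{size} input, got {x.data.shape[-2:]}")
    return network(x)


def encoder_features(encoder: Encoder | GatedEncoder, images) -> list[Tensor]:
    """Per-level latent feature maps, for skips and discriminators."""
    return encoder.features(_to_nchw(images))


def predict_depth(network: DepthNet, images,
                  encoder: Encoder | GatedEncoder | None = None) -> np.ndarray:
    """Full-resolution depth (N, H, W), optionally through a swapped encoder."""
    network.eval()
    x = _to_nchw(images, dtype=network.param_dtype())
    feats = (encoder or network.encoder).features(x)
    pred = network.decoder(feats, x)
    return pred.full.data[:, 0]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, network: DepthNet, phase: str,
                    extra: dict | None = None) -> None:
    """Single-file archive: weights + config + phase tag {synthetic, adapted}."""
    meta = {"config": dataclasses.asdict(network.config), "phase": phase,
            "extra": extra or {}}
    meta_json = json.dumps(meta, sort_keys=True)
    state = {f"net.{k}": v for k, v in network.state_dict().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        meta_json.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple[DepthNet, str]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = DepthNet(NetworkConfig(**meta["config"]), seed=0)
        net.load_state_dict({k[4:]: data[k] for k in data.files
                             if k.startswith("net.")})
    return net, meta["phase"]
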