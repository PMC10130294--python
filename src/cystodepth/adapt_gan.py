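"""Adversarial domain adaptation of the gated encoder.

Phase 2 of the method: the depth network stays fixed; only the gated
residual blocks inserted into the encoder copy F_R are trained so that,
for images of the new (real) domain, F_R produces latent features that
per-level patch discriminators cannot tell apart from the frozen source
encoder F_S's features on synthetic images.  Discrimination happens at
the three deepest encoder levels (3-5), where features are most abstract;
shallower levels keep their synthetic statistics.

Training alternates one discriminator ascent step on L_A with one
generator descent step on the non-saturating surrogate.  Batch
normalization statistics are frozen in both encoders throughout, the
gate scalars are clamped below the tan pole after every step, and the
whole trajectory (gate values, both losses, probe-batch prediction
spread) is logged for the stability diagnostics: without gating the
generator tends to collapse onto an input-independent "feasible" output,
which the mode-collapse score makes measurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .depth_net import DepthNet, GatedEncoderPair, _to_nchw
from .loss_suite import discriminator_loss, generator_loss
from .nn import Tensor

__all__ = [
    "PatchDiscriminator", "DiscriminatorSet", "AdaptConfig", "AdaptationLog",
    "build_discriminators", "adapt_domain", "mode_collapse_score",
]

ADVERSARIAL_LEVELS = (3, 4, 5)


class PatchDiscriminator(nn.Module):
    """Stride-2 conv stack ending in a sigmoid patch-probability map.

    No normalization layers: the two domains are judged in separate forward
    passes, and batch statistics would let the stack discriminate on the
    batch rather than the features, destabilizing the generator signal.
    """

    def __init__(self, in_ch: int, spatial: int, rng,
                 base_width: int = 64, depth: int = 3):
        super().__init__()
        self.layers = []
        ch = in_ch
        width = base_width
        size = spatial
        for _ in range(depth):
            if size < 2:
                break  # feature map too small for further striding
            self.layers.append(nn.Conv2d(ch, width, 4, stride=2, padding=1, rng=rng))
            ch = width
            width = min(width * 2, 8 * base_width)
            size //= 2
        self.final = nn.Conv2d(ch, 1, 3, stride=1, padding=1, rng=rng)
        self.out_spatial = size

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).leaky_relu(0.2)
        return self.final(x).sigmoid()


class DiscriminatorSet(nn.Module):
    """Independent patch discriminators for encoder levels 3, 4, 5."""

    def __init__(self, discs: dict[int, PatchDiscriminator]):
        super().__init__()
        self.levels = sorted(discs)
        self.discs = [discs[l] for l in self.levels]

    def __call__(self, features: dict[int, Tensor]) -> dict[int, Tensor]:
        return {l: d(features[l]) for l, d in zip(self.levels, self.discs)}


def build_discriminators(level_specs: dict[int, tuple[int, int]], seed: int,
                         base_width: int = 64, depth: int = 3,
                         allow_any_levels: bool = False) -> DiscriminatorSet:
    """Create the discriminator set from {level: (channels, spatial size)}.

    The level set must be {3, 4, 5} unless ``allow_any_levels`` is given
    for ablation experiments.
    """
    if not allow_any_levels and set(level_specs) != set(ADVERSARIAL_LEVELS):
        raise ValueError(
            f"discriminators are applied at levels {set(ADVERSARIAL_LEVELS)}, "
            f"got {set(level_specs)}")
    rng = np.random.default_rng(seed)
    discs = {l: PatchDiscriminator(ch, spatial, rng, base_width, depth)
             for l, (ch, spatial) in sorted(level_specs.items())}
    return DiscriminatorSet(discs)


# ---------------------------------------------------------------------------
# Adaptation loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdaptConfig:
    steps: int = 200
    batch_size: int = 8
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    grad_clip: float = 1.0
    gating: bool = True
    ungated_alpha: float = np.pi / 4   # tan = 1: gates pinned fully open
    probe_interval: int = 25
    probe_size: int = 4
    saturating_generator: bool = False


@dataclass
class AdaptationLog:
    steps: list[int] = field(default_factory=list)
    alphas: list[list[float]] = field(default_factory=list)
    disc_loss: list[float] = field(default_factory=list)
    gen_loss: list[float] = field(default_factory=list)
    probe_steps: list[int] = field(default_factory=list)
    probe_variance: list[float] = field(default_factory=list)
    probe_collapse_score: list[float] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        recs = []
        for i, s in enumerate(self.steps):
            recs.append({"step": s, "disc_loss": self.disc_loss[i],
                         "gen_loss": self.gen_loss[i],
                         **{f"alpha_{j + 1}": a
                            for j, a in enumerate(self.alphas[i])}})
        return recs


class AdaptationDiverged(RuntimeError):
    """Raised on a non-finite loss; carries the log flushed so far."""

    def __init__(self, message: str, log: AdaptationLog):
        super().__init__(message)
        self.log = log


def _adversarial_features(feats: list[Tensor],
                          detach: bool = False) -> dict[int, Tensor]:
    out = {l: feats[l - 1] for l in ADVERSARIAL_LEVELS}
    if detach:
        out = {l: t.detach() for l, t in out.items()}
    return out


def adapt_domain(pair: GatedEncoderPair, discs: DiscriminatorSet,
                 synth_images: np.ndarray, real_images: np.ndarray,
                 adapt_config: AdaptConfig, seed: int,
                 net: DepthNet | None = None
                 ) -> tuple[GatedEncoderPair, AdaptationLog]:
    """Alternating GAN training of the gated blocks against the discriminators.

    synth_images / real_images: (N, H, W, 3) arrays in [0, 1].  When `net`
    is given, a fixed probe batch of distinct real images is pushed through
    the adapted encoder + frozen decoder at every probe interval, and the
    spread of the predicted depth maps is logged (mode-collapse diagnostic).
    F_S, the decoder and all base F_R weights stay frozen; with gating
    disabled, the gates are pinned fully open from step 0 instead.
    """
    if len(real_images) == 0:
        raise ValueError("real_images is empty")
    cfg = adapt_config
    rng = np.random.default_rng(seed)
    log = AdaptationLog()

    f_r = pair.f_r
    if not cfg.gating:
        # Ablation: gates removed — pinned fully open (tan(pi/4) = 1) and
        # not trainable, with the blocks' own parameters trainable as usual.
        for b in f_r.blocks:
            b.alpha.data = np.asarray(cfg.ungated_alpha,
                                      dtype=b.alpha.data.dtype)
            b.alpha.requires_grad = False

    pair.eval()   # frozen normalization statistics throughout
    discs.train()
    dt = f_r.param_dtype()
    discs.to_dtype(dt)

    gen_params = f_r.trainable_parameters()
    disc_params = discs.trainable_parameters()
    gen_opt = nn.Adam(gen_params, lr=cfg.lr, betas=cfg.betas,
                      grad_clip=cfg.grad_clip)
    disc_opt = nn.Adam(disc_params, lr=cfg.lr, betas=cfg.betas,
                       grad_clip=cfg.grad_clip)

    probe = None
    if net is not None and len(real_images) >= 2:
        k = min(cfg.probe_size, len(real_images))
        probe = real_images[:k]

    def probe_snapshot(step: int) -> None:
        if probe is None:
            return
        x = _to_nchw(probe, dtype=dt)
        feats = f_r.features(x)
        preds = net.decoder(feats, x).full.data[:, 0]
        log.probe_steps.append(step)
        log.probe_variance.append(float(np.var(preds.mean(axis=(1, 2)))))
        log.probe_collapse_score.append(mode_collapse_score(preds))

    probe_snapshot(0)
    for step in range(1, cfg.steps + 1):
        si = rng.integers(0, len(synth_images), size=cfg.batch_size)
        ri = rng.integers(0, len(real_images), size=cfg.batch_size)
        xs = _to_nchw(synth_images[si], dtype=dt)
        xr = _to_nchw(real_images[ri], dtype=dt)

        # --- discriminator ascent on L_A (encoder features detached) ---
        fs = _adversarial_features(pair.f_s.features(xs), detach=True)
        fr = _adversarial_features(f_r.features(xr), detach=True)
        d_loss = discriminator_loss(discs(fs), discs(fr))
        disc_opt.zero_grad()
        gen_opt.zero_grad()
        d_loss.backward()
        disc_opt.step()

        # --- generator descent on the (non-)saturating surrogate ---
        fr_live = _adversarial_features(f_r.features(xr))
        g_loss = generator_loss(discs(fr_live), cfg.saturating_generator)
        disc_opt.zero_grad()
        gen_opt.zero_grad()
        g_loss.backward()
        gen_opt.step()
        f_r.clamp_alphas()

        log.steps.append(step)
        log.alphas.append(f_r.alphas())
        log.disc_loss.append(float(d_loss.data))
        log.gen_loss.append(float(g_loss.data))
        if not (np.isfinite(d_loss.data) and np.isfinite(g_loss.data)):
            raise AdaptationDiverged(
                f"non-finite adversarial loss at step {step}", log)
        if step % cfg.probe_interval == 0 or step == cfg.steps:
            probe_snapshot(step)

    return pair, log


def mode_collapse_score(predictions, mask: np.ndarray | None = None) -> float:
    """Mean pairwise normalized RMS difference between predicted depth maps.

    0 means every probe input produced the same prediction (full mode
    collapse); healthy input-dependent predictions score well above 0.
    The normalizer is the mean absolute prediction over the probe batch,
    so maps differing by a constant offset equal to that mean score 1.
    """
    preds = np.asarray(predictions, dtype=np.float64)
    if preds.ndim == 2:
        preds = preds[None]
    if preds.shape[0] < 2:
        raise ValueError("mode_collapse_score needs at least 2 probe inputs")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        flat = preds[:, sel]
    else:
        flat = preds.reshape(preds.shape[0], -1)
    norm = float(np.mean(np.abs(flat)))
    if norm == 0.0:
        return 0.0
    scores = [np.sqrt(np.mean((flat[i] - flat[j]) ** 2)) / norm
              for i, j in itertools.combinations(range(flat.shape[0]), 2)]
    return float(np.mean(scores))
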