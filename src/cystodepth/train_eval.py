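"""Supervised depth training, evaluation, and the two-domain toy experiment.

Phase 1 trains the encoder-decoder on rendered synthetic frames with the
multi-level BerHu + log-gradient objective; the retained checkpoint is the
epoch with the lowest validation RMSE.  Evaluation pools the squared error
over every valid pixel of a split and reports the root in millimetres.

``toy_adaptation_experiment`` packages the whole method at desk scale:
two synthetic domains are rendered — S with the plain material and R with
shifted texture and brightness statistics — phase 1 is trained on S, and
the gated encoder is adversarially adapted to R using only R's images.
Because R is itself synthetic, its held-out ground-truth depth lets the
adaptation be scored (something impossible on clinical video), and a
parallel run with the gates pinned open quantifies the stabilizing effect
of gating via the mode-collapse score.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .adapt_gan import (AdaptConfig, build_discriminators, adapt_domain,
                        mode_collapse_score, ADVERSARIAL_LEVELS)
from .depth_net import (DepthNet, NetworkConfig, build_depth_network,
                        insert_gated_blocks, predict_depth, _to_nchw)
from .loss_suite import LossWeights, multiscale_loss
from .scene_forge import (DatasetConfig, DatasetManifest, PoseConfig,
                          SceneGenConfig, generate_dataset, load_frame)

__all__ = [
    "TrainConfig", "EvalReport", "ToyExperimentConfig",
    "train_supervised", "evaluate_rmse", "toy_adaptation_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1
    batch_size: int = 8
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class EvalReport:
    rmse_mm: float
    per_frame_rmse: list[float]
    n_frames: int


def _load_split(manifest: DatasetManifest, split: str
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    recs = manifest.frames_for(split)
    if not recs:
        raise ValueError(f"split {split!r} is empty")
    rgbs, depths, masks = [], [], []
    for rec in recs:
        fr = load_frame(manifest, rec)
        rgbs.append(fr.rgb)
        depths.append(fr.depth)
        masks.append(fr.mask)
    return np.stack(rgbs), np.stack(depths), np.stack(masks)


def _batched_predict(network: DepthNet, images: np.ndarray,
                     batch_size: int = 8, encoder=None) -> np.ndarray:
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(predict_depth(network, images[i:i + batch_size],
                                  encoder=encoder))
    return np.concatenate(outs, axis=0)


def evaluate_rmse(network: DepthNet, manifest: DatasetManifest,
                  split: str = "val", encoder=None) -> EvalReport:
    """RMSE (mm) pooled over all valid pixels of a split."""
    images, depths, masks = _load_split(manifest, split)
    if np.any(masks & (depths <= 0)):
        raise ValueError("a frame lacks ground-truth depth inside its mask")
    preds = _batched_predict(network, images, encoder=encoder)
    sq = (preds - depths) ** 2
    pooled = float(np.sqrt(sq[masks].mean()))
    per_frame = [float(np.sqrt(sq[i][masks[i]].mean()))
                 for i in range(len(images))]
    return EvalReport(rmse_mm=pooled, per_frame_rmse=per_frame,
                      n_frames=len(images))


def train_supervised(network: DepthNet, manifest: DatasetManifest,
                     config: TrainConfig) -> tuple[dict, dict]:
    """Minimize the multi-level loss on the train split.

    Returns (checkpoint, history): checkpoint holds the state and epoch of
    the lowest validation RMSE; history records the validation RMSE before
    training ("epoch 0") and per-epoch train loss / val RMSE.  The network
    is left loaded with the checkpoint weights.
    """
    images, depths, masks = _load_split(manifest, "train")
    rng = np.random.default_rng(config.seed)
    network.to_dtype(np.float32)  # CPU training speed; metrics stay float64
    opt = nn.Adam(network.trainable_parameters(), lr=config.lr,
                  betas=config.betas)

    history: dict = {"train_loss": [], "val_rmse": [],
                     "initial_val_rmse": evaluate_rmse(
                         network, manifest, "val").rmse_mm}
    best = {"epoch": 0, "val_rmse": np.inf, "state": None}

    n = len(images)
    for epoch in range(1, config.epochs + 1):
        network.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = _to_nchw(images[idx], dtype=np.float32)
            pred = network(x)
            breakdown = multiscale_loss(depths[idx], pred, masks[idx],
                                        config.weights)
            opt.zero_grad()
            breakdown.total.backward()
            opt.step()
            losses.append(float(breakdown.total.data))
        val = evaluate_rmse(network, manifest, "val").rmse_mm
        history["train_loss"].append(float(np.mean(losses)))
        history["val_rmse"].append(val)
        if val < best["val_rmse"]:
            best = {"epoch": epoch, "val_rmse": val,
                    "state": network.state_dict()}
    if best["state"] is not None:
        network.load_state_dict(best["state"])
    checkpoint = {"epoch": best["epoch"], "val_rmse": best["val_rmse"],
                  "state": best["state"]}
    return checkpoint, history


# ---------------------------------------------------------------------------
# The packaged two-domain experiment
# ---------------------------------------------------------------------------

def _shifted_scene_config(base: SceneGenConfig) -> SceneGenConfig:
    """Domain R: same geometry statistics, shifted appearance."""
    return dataclasses.replace(
        base,
        material="textured",
        base_color_low=(0.75, 0.18, 0.14),
        base_color_high=(0.95, 0.35, 0.28),
        vessel_contrast_range=(0.6, 0.9),
        brightness_scale_range=(1.2, 1.5),
        intensity_range=(140.0, 320.0),
    )


@dataclass(frozen=True)
class ToyExperimentConfig:
    image_size: int = 64
    workdir: str = "scratch/toy_experiment"
    # domain S (plain-material source domain)
    s_models: int = 6
    s_frames_per_model: int = 20
    s_val_models: int = 1
    # domain R (appearance-shifted target domain)
    r_models: int = 3
    r_frames_per_model: int = 20
    r_eval_models: int = 1
    net: NetworkConfig = field(default_factory=lambda: NetworkConfig(
        n_encoder_levels=5, base_channels=8, channel_cap=64, input_size=64,
        init_depth_mm=25.0))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=20, batch_size=8, lr=1e-3))
    adapt: AdaptConfig = field(default_factory=lambda: AdaptConfig(
        steps=300, batch_size=8, lr=2e-4, probe_interval=75, probe_size=8))
    disc_base_width: int = 32


def _render_domain(cfg: ToyExperimentConfig, scene_cfg: SceneGenConfig,
                   n_models: int, frames_per_model: int, n_val: int,
                   materials: tuple[str, ...], out_dir: str,
                   seed: int) -> DatasetManifest:
    ds_cfg = DatasetConfig(
        n_models=n_models,
        images_per_model_per_material=frames_per_model // len(materials),
        out_dir=out_dir, image_size=cfg.image_size,
        n_val_models=n_val, n_test_models=0,
        scene=scene_cfg,
        pose=PoseConfig(wall_distance_range=(5.0, 25.0)),
        materials=materials)
    return generate_dataset(ds_cfg, seed)


def toy_adaptation_experiment(experiment_config: ToyExperimentConfig | None,
                              seed: int) -> dict:
    """Run the full two-phase method on two synthetic domains; return a report.

    Report keys: unadapted/adapted RMSE on domain R (mm), the gate
    trajectories (5 per-level alpha series starting at 0), and final
    mode-collapse scores for the gated run and the gates-pinned-open
    ablation.
    """
    cfg = experiment_config or ToyExperimentConfig()
    ss = np.random.SeedSequence(seed)
    s_data, s_train, s_adapt, s_gated, s_ungated = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]

    os.makedirs(cfg.workdir, exist_ok=True)
    base_scene = dataclasses.replace(SceneGenConfig(), material="plain")
    man_s = _render_domain(cfg, base_scene, cfg.s_models,
                           cfg.s_frames_per_model, cfg.s_val_models,
                           ("plain",), os.path.join(cfg.workdir, "domain_s"),
                           s_data)
    man_r = _render_domain(cfg, _shifted_scene_config(base_scene),
                           cfg.r_models, cfg.r_frames_per_model,
                           cfg.r_eval_models, ("textured",),
                           os.path.join(cfg.workdir, "domain_r"),
                           s_data + 1)

    # phase 1: supervised training on the source domain
    net = build_depth_network(cfg.net, seed=s_train)
    train_cfg = dataclasses.replace(cfg.train, seed=s_train)
    checkpoint, history = train_supervised(net, man_s, train_cfg)

    unadapted = evaluate_rmse(net, man_r, "val")

    s_images, _, _ = _load_split(man_s, "train")
    r_images, _, _ = _load_split(man_r, "train")  # adaptation sees no depth

    level_specs = {l: (cfg.net.channels(l), cfg.image_size // (1 << l))
                   for l in ADVERSARIAL_LEVELS}

    def run_adaptation(gating: bool, run_seed: int):
        pair = insert_gated_blocks(net.encoder, seed=run_seed)
        discs = build_discriminators(level_specs, seed=run_seed + 1,
                                     base_width=cfg.disc_base_width)
        adapt_cfg = dataclasses.replace(cfg.adapt, gating=gating)
        return adapt_domain(pair, discs, s_images, r_images, adapt_cfg,
                            seed=run_seed + 2, net=net)

    pair_gated, log_gated = run_adaptation(True, s_gated)
    adapted = evaluate_rmse(net, man_r, "val", encoder=pair_gated.f_r)
    _, log_ungated = run_adaptation(False, s_ungated)

    alpha_series = list(map(list, zip(*([[0.0] * 5] + log_gated.alphas))))
    return {
        "seed": seed,
        "phase1": {"best_epoch": checkpoint["epoch"],
                   "best_val_rmse_mm": checkpoint["val_rmse"],
                   "initial_val_rmse_mm": history["initial_val_rmse"]},
        "unadapted_rmse_mm": unadapted.rmse_mm,
        "adapted_rmse_mm": adapted.rmse_mm,
        "alpha_trajectories": alpha_series,
        "mode_collapse_score_gated": log_gated.probe_collapse_score[-1],
        "mode_collapse_score_ungated": log_ungated.probe_collapse_score[-1],
        "gated_log": {"disc_loss": log_gated.disc_loss,
                      "gen_loss": log_gated.gen_loss},
        "ungated_log": {"disc_loss": log_ungated.disc_loss,
                        "gen_loss": log_ungated.gen_loss},
    }
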