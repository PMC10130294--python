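# cystodepth

Monocular depth estimation for cystoscopy — endoscopic examination of the
urinary bladder — where stereo rigs and depth sensors cannot fit and the
scene is too dynamic for structure-from-motion. The package implements a
two-phase approach:

1. **Synthetic supervision.** A procedural generator renders bladder-like
   cavities (star-shaped implicit surfaces with lobes, fractal wall
   displacement, polyp-like protrusions, vessel texture, camera-attached
   conical lighting) as RGB images with exact per-pixel depth in
   millimetres. An encoder–decoder network with ICNR-initialized
   sub-pixel upsampling is trained on these renders, supervised at four
   decoder scales with

       L = sum_{l=1..4}  c0 · L_BerHu(D, u(D*_l)) + c1 · L_grad(D, u(D*_l)),

   where the reverse-Huber (BerHu) term uses the threshold
   c = max|D − D*| / 5 and L_grad penalizes forward differences of
   log D − log D*.

2. **Gated adversarial domain adaptation.** To transfer to an unlabeled
   image domain, the trained encoder is duplicated: F_S stays frozen,
   F_R gains one gated residual block per encoder level,

       O_i = R_i(x) · tan(α_i),   α_i initialized to 0,

   so F_R starts exactly equal to F_S and domain corrections fade in as
   the learned gates open (ReZero-style). PatchGAN discriminators at the
   three deepest encoder levels are trained against the gated encoder
   with the objective

       L_A = Σ_{i∈{3,4,5}} E[log A_i(F_Si(I_S))] + E[log(1 − A_i(F_Ri(I_R)))],

   batch-normalization statistics frozen throughout. The gating is what
   keeps this adversarial phase stable: an ablation with the gates pinned
   open degrades toward input-independent predictions (mode collapse),
   which the package quantifies with a probe-batch collapse score.

A frame-quality gate for real endoscopic video (circular field-of-view
fitting, red-dominance, Laplacian-variance sharpness and brightness
thresholds, stride sampling) prepares clinical frames for adaptation.

Everything — including the neural-network machinery (reverse-mode
autodiff, convolutions, batch norm, pixel shuffle, Adam) — runs on numpy
on a single CPU core; every operation is deterministic given its seed.

## Worked example

Run the packaged two-domain experiment: phase 1 trains on a plain-material
synthetic domain S, then the encoder is adapted to a shifted synthetic
domain R (stronger vessels, 2.5× brighter light) using only R's images,
and scored against R's held-out ground truth:

```bash
cystodepth toy-experiment --seed 0 --out report.json --workdir scratch/toy
```

prints (numbers from this exact command on one CPU core):

```json
{"unadapted_rmse_mm": 3.029, "adapted_rmse_mm": 2.804,
 "mode_collapse_score_gated": 0.209, "mode_collapse_score_ungated": 0.156}
```

Reading: applying the synthetic-trained network directly to the shifted
domain costs accuracy (3.03 mm RMSE on 64×64 renders); opening the gates
against the discriminators recovers part of it (2.80 mm) without ever
seeing a depth label from R. The gated run keeps a higher collapse score
(more input-dependent predictions) than the gates-pinned-open ablation,
the packaged counterpart of the gating-stability claim. `report.json`
additionally contains the five α-gate trajectories (all starting at 0)
and both adversarial loss curves.

The other commands mirror the library surface:

```bash
cystodepth render --seed 0 --out data/ --n-models 2 --images 5 --size 128
cystodepth train --manifest data/manifest.json --seed 0 --out ckpt.npz
cystodepth evaluate --ckpt ckpt.npz --manifest data/manifest.json --split val
cystodepth predict --ckpt ckpt.npz --in frames/ --out depths/
cystodepth filter-frames --in frames/ --stride 5 --out kept.json --report reasons.csv
```

## Layout

| module | role |
| --- | --- |
| `cystodepth.scene_forge` | procedural cavities, ray-cast RGB-D rendering, augmentation, dataset I/O and the model-level split |
| `cystodepth.depth_net` | U-Net depth network, ICNR sub-pixel upsampling, gated residual blocks, encoder pair, checkpoints |
| `cystodepth.loss_suite` | BerHu, log-gradient, multi-level and adversarial objectives |
| `cystodepth.adapt_gan` | PatchGAN discriminators, alternating adaptation loop, mode-collapse diagnostics |
| `cystodepth.train_eval` | supervised training, RMSE evaluation, the packaged two-domain experiment |
| `cystodepth.frame_gate` | real-frame stride sampling, circular-mask fitting, quality filters |
| `cystodepth.nn` | numpy autodiff and CNN primitives backing all of the above |

`docs/methods.md` documents the models, defaults and numerical choices in
detail, including what the synthetic domains do and do not emulate.
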