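# Methods

`cystodepth` implements two-phase monocular depth estimation for
endoscopy of the bladder: (1) supervised depth learning on a procedurally
generated synthetic cystoscopic RGB-D domain, and (2) adversarial domain
adaptation of the image encoder to an unlabeled target domain through
gated residual blocks. This note documents the models, the parameters
that matter, the numerical choices, and what the packaged experiments do
and do not demonstrate.

## The synthetic cystoscopic domain

Ground-truth depth cannot be measured inside a real bladder, so the
package renders its own. Each cavity is a *star-shaped implicit surface*:
a radius function of direction from an interior origin,

    rho(d) = r0 + sum_k a_k cos(f_k * phi + phi_k) sin(theta)     (lobes)
           + A * fbm(d * s)                                       (wall noise)
           - sum_j h_j exp(-ang(d, d_j)^2 / (2 sigma_j^2))        (polyps)

with `r0` the base radius (default 25–40 mm, a moderately filled human
bladder), low-frequency lobes making the organ irregular, fractal value
noise (`fbm`, zero-mean, octaves 2–4) wrinkling the wall, and
Gaussian-in-angle protrusions of height `h_j <= r0/2` standing in for
polyps. Star shape guarantees exactly one wall intersection along any ray
from an interior point, which makes depth well defined and lets the
renderer be verified against the closed-form ray–sphere solution in the
undeformed limit.

Sampling-range validation is conservative: a configuration is rejected
whenever the *worst case* sum of perturbation magnitudes could reach the
center, so every sampled cavity satisfies the star-shape invariant by
construction.

**Rendering.** Rays are cast per pixel from a pinhole camera (default
FOV 70°, image 256x256; the packaged experiments use 64x64). The wall hit
is found by stepping until the implicit function changes sign and then
bisecting (45 iterations; residual well below 10^-3 mm). Depth is the
Euclidean camera-to-hit distance in millimetres, matching how ray-trace
render engines emit depth passes and how the RMSE metric is stated.
Shading models an endoscope: two conical spotlights rigidly attached to
the camera at ±2 mm lateral offset (cone half-angle default 50–70°, with
a small 0.05 floor outside the cone), Lambertian reflection with
inverse-square falloff, a fixed small Phong highlight, and a wrap-diffuse
term (weight 0.25, wrap 0.3) as a cheap stand-in for tissue translucency.
Self-shadowing is omitted; with lights co-located with the camera inside
a convex-ish cavity its contribution is minor. Light intensity defaults
(50–130 mm^2-equivalent) put typical wall pixels mid-range at the 5–25 mm
working distances used for pose sampling; close approaches still clip to
white, as real endoscopy footage does.

**Materials.** The plain material is a constant tissue-colored albedo.
The textured material adds vessel-like strokes — level sets of ridged
value noise (`1 - |fbm|` thresholded near 1 form thin curvilinear
networks), blended toward dark red with a sampled contrast — plus low
frequency albedo mottling and a per-scene brightness scale in [0.5, 1.5].

**Poses.** A random center ray is drawn, the camera is placed at a
sampled 5–25 mm from the wall along it, and the viewing direction is
tilted up to 30° away from the ray (the range the source procedure
prescribes). Poses whose requested wall distance exceeds the cavity along
the sampled ray are resampled, with a bounded retry count.

**Augmentation.** Photometric jitter applies to color only; rotation
(0–360°) and translation apply identically to color, depth and mask.
Depth and mask are resampled by nearest neighbor so no values blend
across the circular mask edge; at exact right angles this resampling is a
permutation of the depth values, which the tests exploit. Color is
resampled bilinearly and re-masked.

**Dataset files.** RGB as 8-bit PNG, depth as 16-bit PNG with a mm-per-code
scale in a JSON sidecar (scale fixed per dataset from the configuration's
worst-case geometry so the maximum representable depth maps to code
60000), masks as 8-bit PNG, plus a `manifest.json` listing every frame
and the model-level train/val/test split. Splits are by model: no cavity
contributes frames to two splits.

## The depth network

A U-Net-style encoder–decoder. Encoder level i halves the spatial side
and carries `min(base * 2^(i-1), cap)` channels (defaults: 5 levels, base
32, cap 256; the packaged CPU experiments use base 8, cap 64). Each level
is a strided conv + refining conv, both batch-normalized with ReLU.

The decoder mirrors it. Every upsampling stage is a *sub-pixel
convolution*: a 3x3 conv producing 4x channels followed by a 2x pixel
shuffle, with ICNR initialization — the four kernels feeding one output
channel start identical, so at initialization the stage is exactly
nearest-neighbor upsampling of a learned stride-1 conv and produces no
checkerboard pattern. The stage at each resolution concatenates the
same-size encoder features (the input image at full resolution, where the
encoder keeps no features).

During training the decoder is supervised at four levels l = 1..4 (side
= input / 2^(l-1)). Each depth head is a 3x3 conv with a softplus, so
predictions are non-negative (required by the log in the gradient loss);
the head bias starts at 25 so initial predictions sit at a plausible
cavity depth rather than at zero.

## Losses

* **BerHu (reverse Huber)**: per-pixel |d| below the threshold c, and
  (d^2 + c^2)/(2c) above it, continuous at |d| = c, with
  c = max|d| / 5 computed over the valid pixels of the whole batch (a
  per-image option exists). The mean is taken over valid pixels so the
  loss scale is independent of mask size. When the prediction is perfect
  (c = 0) the loss is exactly 0.
* **Log-gradient**: y = log D - log D*, penalizing squared forward
  differences of y over stencil positions whose two pixels are both
  valid. Invariant to global rescaling of either map; encourages smooth
  depth where tissue is smooth.
* **Multi-level total**: sum over l = 1..4 of c0 * BerHu + c1 * L_grad
  after bilinear upsampling (align_corners=false) of each predicted level
  to the ground-truth resolution. Defaults c0 = 1.0, c1 = 0.5 (the
  weighting is not prescribed anywhere; both are config keys). The sum is
  a literal sum over levels, not an average.
* **Adversarial**: L_A = sum over levels i in {3,4,5} of
  E[log A_i(F_Si(I_S))] + E[log(1 - A_i(F_Ri(I_R)))], expectations taken
  over batch and patch positions, outputs epsilon-clamped at 10^-7 before
  the logs. Discriminators ascend L_A; the generator descends the
  non-saturating surrogate -sum_i E[log A_i(F_Ri(I_R))] (the saturating
  form is available by flag). L_A <= 0 always, approaching 0 only for a
  perfect discriminator; three levels of constant 0.5 outputs give
  exactly -6 ln 2.

## Gated adaptation

After phase 1 the whole network is frozen. The encoder is duplicated:
F_S stays fixed as the reference; F_R gains one gated residual block at
the output of each of the five encoder levels,

    out = x + R(x) * tan(alpha),

with R two normalized 3x3 convs and alpha a learnable scalar initialized
at 0 (ReZero-style). tan — as specified, not tanh — is kept, with
|alpha| clamped below pi/2 - 10^-3 after every optimizer step; a tanh
variant exists for ablation. At alpha = 0 the gate is exactly closed:
F_R reproduces F_S bit for bit, which the tests assert end to end. Only
the blocks and their gates are trainable; batch-normalization running
statistics are frozen in both encoders for the whole of phase 2.

Patch discriminators judge level-3..5 features (the three deepest
levels). They are stacks of stride-2 convs with leaky ReLU ending in a
1-channel sigmoid patch map — deliberately *without* normalization
layers: the two domains pass through the discriminator in separate
forward passes, and batch normalization lets the stack discriminate on
batch statistics rather than features, which in development destabilized
the generator signal badly enough to erase the benefit of adaptation.
Training alternates one discriminator step and one generator step (Adam,
beta1 = 0.5, lr 2e-4 for both players, batch 8, element-wise gradient
clip 1.0 — none of these are prescribed by the source; all are config
keys).

The *ungated ablation* pins every gate fully open from step 0
(alpha = pi/4, tan = 1, gates not trainable) with the block convs
trainable — one of the two plausible readings of "gates removed"; the
alternative (unfreezing the whole encoder) is noted as such. The
mode-collapse score quantifies the known failure mode: the mean pairwise
RMS difference between predicted depth maps for a fixed probe batch of
distinct inputs, normalized by the mean absolute prediction. 0 means the
network predicts the same map regardless of input.

## The packaged two-domain experiment

Clinical video has no ground truth, so adaptation quality is measured on
a second *synthetic* domain R with shifted appearance statistics: the
textured material with stronger vessels (contrast 0.6–0.9), redder and
brighter albedo, brightness scale 1.2–1.5 and roughly 2.5x brighter
lights (intensity 140–320 vs 50–130) — geometry statistics unchanged.
Phase 1 trains on domain S (plain material, 6 models x 20 frames, 20
epochs); the unadapted network is evaluated on R's held-out model; gated
adaptation then uses only R's *images* (40 frames from 2 models), and the
adapted encoder is evaluated against R's held-out ground truth. A
parallel ungated run provides the stability contrast. Problem sizes
(64x64 images, base width 8, 300 adaptation steps, 8 probe images) are
the package's desk-scale choices; they keep a full experiment around
three minutes on one CPU core.

What passing shows: the adversarial phase aligns target-domain latent
features well enough to recover accuracy lost to an appearance shift,
and zero-initialized gates keep that process stable where the ungated
variant degrades toward input-independent output. What it does not show:
performance on clinical cystoscopy video — the synthetic shift is far
tamer than the synthetic-to-real gap, there are no instruments, bubbles,
debris or interlacing artifacts, and polyp texture realism is limited.

## Training details and numerics

* Hand-rolled reverse-mode autodiff on numpy backs all networks; every
  spatial primitive (conv via im2col, batch norm in both statistics
  modes, pixel shuffle, bilinear resize) is validated against central
  finite differences in the test suite.
* Float64 is the numeric default; the training loops cast the model to
  float32, which roughly halves CPU time without affecting any tested
  contract (the gate identity remains exact in either precision).
  Reported metrics (RMSE, losses) are computed in float64.
* Supervised phase: Adam (beta1 = 0.9), lr 1e-4 default; the packaged
  64x64 experiments use lr 1e-3, chosen for the small network and short
  schedule. The retained checkpoint is the epoch with the lowest
  validation RMSE; the pre-training validation RMSE is recorded as the
  epoch-0 reference.
* Evaluation RMSE pools squared error over every valid pixel of a split
  before taking the root; per-frame RMSEs are reported alongside.
* Every operation is a pure function of its inputs and an explicit seed;
  dataset generation, training histories and manifests are bit-for-bit
  reproducible for a fixed (config, seed) pair.

## Frame-quality gating of real video

For real frames (already extracted and deinterlaced upstream), the
package stride-samples the stream (default every 5th frame), fits the
circular field-of-view mask (centroid of non-black pixels; radius from
the 95th radial percentile debiased by 1/sqrt(0.95), clamped to the
frame), and measures, over the mask interior with a 2-pixel boundary ring
excluded: red-channel dominance fraction (inside-the-bladder cue),
variance of the Laplacian on 8-bit grayscale (sharpness), mean brightness
and near-white saturation. Frames failing any threshold are excluded with
the first failing test as the recorded reason. Thresholds (red >= 0.5,
Laplacian variance >= 25, brightness in [0.08, 0.9]) pin the packaged
fixtures and are not clinically calibrated values.

## Known limitations

* The procedural cavity is smooth and closed; resection instruments,
  bubbles, debris and fluid turbidity are absent by design.
* Subsurface scattering is approximated by a wrap term; no physically
  based light transport.
* The adversarial phase at desk scale is noisy; the packaged experiment
  reports medians over seeds for this reason, and single runs can
  deviate.
* The exact layer dimensions of the networks in the source line of work
  are not public; channel widths here are chosen to keep the default
  256x256 model under ~20 M parameters.
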