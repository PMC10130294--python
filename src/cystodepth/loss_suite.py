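"""Training objectives for depth regression and adversarial adaptation.

Supervised depth loss
---------------------
The reverse Huber (BerHu) loss treats a per-pixel depth error d = D - D*
as absolute error up to a threshold c and as scaled squared error above it:

    berhu(d) = |d|                  if |d| <= c
             = (d^2 + c^2) / (2c)   otherwise,

with c = (1/5) * max |d| over the valid pixels of the evaluated batch.
The two branches meet at |d| = c, so the loss is continuous, L1-like for
small errors and L2-like for outliers.  A gradient smoothness term acts on
y = log D - log D*: forward differences of y are squared and averaged over
stencil positions whose pixels are both valid, which penalizes spurious
depth edges while being invariant to a global depth rescaling of either
map.  The total supervised loss sums c0 * BerHu + c1 * L_grad over the
four decoder levels, after bilinear upsampling of each predicted map to
the ground-truth resolution.

Adversarial objective
---------------------
For domain adaptation, per-level patch discriminators A_i (i in {3,4,5})
judge encoder features of the frozen source encoder F_S on synthetic
images against those of the gated encoder F_R on real images:

    L_A = sum_i E[log A_i(F_Si(I_S))] + E[log(1 - A_i(F_Ri(I_R)))].

Discriminators ascend L_A; the generator (the gated blocks of F_R)
descends the non-saturating surrogate -sum_i E[log A_i(F_Ri(I_R))].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossWeights", "LossBreakdown",
    "berhu_loss", "gradient_loss", "multiscale_loss", "upsample_bilinear",
    "adversarial_objective", "discriminator_loss", "generator_loss",
]

PROB_EPS = 1e-7  # discriminator outputs clamped to [eps, 1-eps] before logs
BERHU_FRACTION = 0.2  # c = max|d| / 5


@dataclass(frozen=True)
class LossWeights:
    c0: float = 1.0   # BerHu weight
    c1: float = 0.5   # gradient-smoothness weight

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    total: Tensor
    per_level: dict[int, dict[str, float]] = field(default_factory=dict)
    n_valid: int = 0


def _prep(D, D_star, mask) -> tuple[np.ndarray, Tensor, np.ndarray]:
    D = np.asarray(D, dtype=np.float64)
    D_star = nn.as_tensor(D_star)
    if D_star.data.shape != D.shape:
        raise ValueError(
            f"shape mismatch: D {D.shape} vs D* {D_star.data.shape}")
    if mask is None:
        mask = np.ones(D.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != D.shape:
        raise ValueError(f"mask shape {mask.shape} does not match {D.shape}")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return D, D_star, mask


def berhu_loss(D, D_star, mask=None, *,
               per_image: bool = False) -> tuple[Tensor, float]:
    """Mean BerHu loss over valid pixels and the threshold c used (mm).

    c is computed over the whole batch by default; ``per_image`` recomputes
    it per leading-axis element instead.
    """
    D, D_star, mask = _prep(D, D_star, mask)
    diff = nn.as_tensor(D) - D_star
    absdiff = diff.abs()

    if per_image and D.ndim > 2:
        flat = np.abs(D - D_star.data).reshape(D.shape[0], -1)
        mflat = mask.reshape(D.shape[0], -1)
        c_arr = np.array([flat[i, mflat[i]].max() if mflat[i].any() else 0.0
                          for i in range(D.shape[0])]) * BERHU_FRACTION
        c_full = np.broadcast_to(
            c_arr.reshape((-1,) + (1,) * (D.ndim - 1)), D.shape)
        c_used = float(c_arr.max())
    else:
        c_used = float(np.abs(D - D_star.data)[mask].max()) * BERHU_FRACTION
        c_full = np.full(D.shape, c_used)

    l1_region = (np.abs(D - D_star.data) <= c_full) | (c_full == 0.0)
    c_safe = np.where(c_full > 0, c_full, 1.0)  # quad branch unused when c=0
    quad = (diff * diff + c_full ** 2) / (2.0 * c_safe)
    per_pixel = absdiff * l1_region.astype(float) + quad * (~l1_region).astype(float)
    loss = (per_pixel * mask.astype(float)).sum() * (1.0 / mask.sum())
    return loss, c_used


def gradient_loss(D, D_star, mask=None) -> Tensor:
    """Mean squared forward-difference gradient of log D - log D*.

    Only stencil positions with both pixels valid contribute; requires
    strictly positive depth inside the mask.
    """
    D, D_star, mask = _prep(D, D_star, mask)
    if np.any(D[mask] <= 0) or np.any(D_star.data[mask] <= 0):
        raise ValueError("gradient_loss requires positive depths inside the mask")
    # log evaluated everywhere; masked-out entries are replaced by 1 so the
    # log is defined, then excluded by the validity stencils
    safe_gt = np.where(mask, D, 1.0)
    safe_pred = D_star * nn.Tensor(mask.astype(float)) + nn.Tensor(
        (~mask).astype(float))
    y = nn.Tensor(np.log(safe_gt)) - safe_pred.log()

    ax_x, ax_y = y.ndim - 1, y.ndim - 2
    sl = [slice(None)] * y.ndim

    def fdiff(t, axis):
        lo = sl.copy(); hi = sl.copy()
        lo[axis] = slice(None, -1); hi[axis] = slice(1, None)
        return t[tuple(hi)] - t[tuple(lo)]

    def valid(axis):
        lo = sl.copy(); hi = sl.copy()
        lo[axis] = slice(None, -1); hi[axis] = slice(1, None)
        return mask[tuple(hi)] & mask[tuple(lo)]

    gx, vx = fdiff(y, ax_x), valid(ax_x)
    gy, vy = fdiff(y, ax_y), valid(ax_y)
    n = int(vx.sum() + vy.sum())
    if n == 0:
        return nn.Tensor(0.0)
    total = (gx * gx * nn.Tensor(vx.astype(float))).sum() \
        + (gy * gy * nn.Tensor(vy.astype(float))).sum()
    return total * (1.0 / n)


def upsample_bilinear(depth_map, target_size: tuple[int, int]) -> Tensor:
    """Bilinear upsampling (align_corners=False); refuses to downscale."""
    t = nn.as_tensor(depth_map)
    if target_size[0] < t.data.shape[-2] or target_size[1] < t.data.shape[-1]:
        raise ValueError("target size smaller than source: refusing to downscale")
    return nn.upsample_bilinear(t, target_size)


def multiscale_loss(D, preds, mask=None,
                    weights: LossWeights | None = None) -> LossBreakdown:
    """Eq.-style multi-level objective: sum_l c0*BerHu + c1*L_grad.

    Each predicted level is bilinearly upsampled to the resolution of the
    ground truth D before both terms are evaluated.
    """
    w = weights or LossWeights()
    D = np.asarray(D, dtype=np.float64)
    target = (D.shape[-2], D.shape[-1])
    breakdown = LossBreakdown(total=nn.Tensor(0.0))
    total: Tensor | None = None
    for level, pred in preds.levels:
        p = pred
        if p.data.ndim == 4 and D.ndim == 3:
            p = p.reshape(p.data.shape[0], *p.data.shape[2:])
        elif p.data.ndim == 4 and D.ndim == 2:
            p = p.reshape(*p.data.shape[2:])
        up = upsample_bilinear(p, target)
        b, c = berhu_loss(D, up, mask)
        g = gradient_loss(D, up, mask)
        term = b * w.c0 + g * w.c1
        total = term if total is None else total + term
        breakdown.per_level[level] = {
            "berhu": float(b.data), "grad": float(g.data), "c": c}
    if total is None:
        raise ValueError("prediction carries no levels")
    breakdown.total = total
    breakdown.n_valid = int(np.count_nonzero(
        np.ones(D.shape) if mask is None else mask))
    return breakdown


# ---------------------------------------------------------------------------
# Adversarial objective
# ---------------------------------------------------------------------------

def _clamped_log(p: Tensor) -> Tensor:
    return p.clamp(PROB_EPS, 1.0 - PROB_EPS).log()


def adversarial_objective(A_outputs_synth: dict[int, Tensor],
                          A_outputs_real: dict[int, Tensor]) -> Tensor:
    """L_A = sum_i E[log A_i(synth)] + E[log(1 - A_i(real))], i in {3,4,5}.

    Expectations are means over batch and patch positions.  L_A <= 0, with
    the supremum 0 approached only by a perfect discriminator.
    """
    if set(A_outputs_synth) != set(A_outputs_real):
        raise ValueError("synthetic and real outputs must cover the same levels")
    total: Tensor | None = None
    for level in sorted(A_outputs_synth):
        a_s, a_r = A_outputs_synth[level], A_outputs_real[level]
        term = _clamped_log(a_s).mean() + _clamped_log(1.0 - a_r).mean()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no discriminator outputs provided")
    return total


def discriminator_loss(A_outputs_synth, A_outputs_real) -> Tensor:
    """Discriminators maximize L_A; implemented as minimizing -L_A."""
    return -adversarial_objective(A_outputs_synth, A_outputs_real)


def generator_loss(A_outputs_real: dict[int, Tensor],
                   saturating: bool = False) -> Tensor:
    """Generator objective on real-domain features.

    Non-saturating form (default): minimize -sum_i E[log A_i(F_Ri(I_R))].
    Saturating form: minimize sum_i E[log(1 - A_i(F_Ri(I_R)))].
    """
    total: Tensor | None = None
    for level in sorted(A_outputs_real):
        a_r = A_outputs_real[level]
        term = _clamped_log(1.0 - a_r).mean() if saturating \
            else -_clamped_log(a_r).mean()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no discriminator outputs provided")
    return total
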