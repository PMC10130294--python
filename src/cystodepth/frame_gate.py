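"""Ingestion and quality gating of real endoscopic video frames.

Clinical cystoscopy video yields many frames that are useless for
training: the endoscope may be outside the body, the image blurred by
motion or fluid, or the scene under- or over-exposed.  Given frames
already extracted (and deinterlaced) from video, this module

1. subsamples the frame stream at a fixed stride,
2. fits the circular endoscopic field-of-view mask,
3. measures per-frame quality — red-channel dominance (inside-the-bladder
   cue), Laplacian variance (sharpness), mean brightness, saturation —
4. keeps frames passing all thresholds, recording the first failing test
   for every exclusion.

Thresholds are configuration, not clinical constants; the defaults are
documented in :class:`FilterThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameQuality", "FilterThresholds",
    "sample_frames", "fit_circular_mask", "frame_quality", "select_frames",
]


@dataclass(frozen=True)
class FrameQuality:
    center: tuple[float, float]      # (row, col) of the fitted circle, px
    radius: float                    # px
    red_fraction: float              # fraction of masked px with dominant red
    laplacian_variance: float        # sharpness (intensity^2, 8-bit gray scale)
    mean_brightness: float           # [0, 1]
    saturated_fraction: float        # fraction of masked px near full white


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults pin the packaged fixtures, not clinically tuned values."""
    min_red_fraction: float = 0.5
    min_laplacian_variance: float = 25.0   # on 8-bit grayscale
    min_brightness: float = 0.08
    max_brightness: float = 0.9
    max_saturated_fraction: float = 0.5
    red_margin: float = 0.04               # red must exceed max(G,B) by this


def sample_frames(paths: Sequence, stride: int) -> list:
    """Every stride-th frame: indices 0, stride, 2*stride, ..."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return list(paths[::stride])


def _to_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.clip(img, 0.0, 1.0)


def fit_circular_mask(image: np.ndarray, black_threshold: float = 0.04
                      ) -> tuple[tuple[float, float], float]:
    """Fit the circular field of view against the black border.

    Near-black pixels are treated as border; the circle is the centroid of
    the non-black region with radius at the 95th percentile of its radial
    distances, clamped to the frame.  An entirely near-black image raises.
    """
    img = _to_float_rgb(image)
    if img.size == 0:
        raise ValueError("empty image")
    bright = img.max(axis=-1) > black_threshold
    if not bright.any():
        raise ValueError("image is entirely near-black; no field of view")
    rows, cols = np.nonzero(bright)
    center = (float(rows.mean()), float(cols.mean()))
    dist = np.hypot(rows - center[0], cols - center[1])
    # p95 of radial distance over a filled disk of radius R is R*sqrt(0.95);
    # debiasing keeps the estimate robust to a few bright outliers while
    # recovering the true radius on a clean disk
    radius = float(np.percentile(dist, 95.0)) / math.sqrt(0.95)
    radius = min(radius, min(img.shape[0], img.shape[1]) / 2.0)
    return center, radius


def _circle_mask(shape: tuple[int, int], center: tuple[float, float],
                 radius: float) -> np.ndarray:
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def frame_quality(image: np.ndarray,
                  mask: tuple[tuple[float, float], float] | np.ndarray,
                  red_margin: float = 0.04) -> FrameQuality:
    """Quality statistics over the masked field of view only."""
    img = _to_float_rgb(image)
    if isinstance(mask, np.ndarray):
        sel = mask.astype(bool)
        rows, cols = np.nonzero(sel)
        center = (float(rows.mean()), float(cols.mean())) if rows.size else (0.0, 0.0)
        radius = float(np.hypot(rows - center[0], cols - center[1]).max()) \
            if rows.size else 0.0
    else:
        center, radius = mask
        sel = _circle_mask(img.shape[:2], center, radius)
    if not sel.any():
        raise ValueError("mask selects no pixels")
    # exclude the mask boundary ring from every statistic: the black border
    # transition is an artifact present in all frames, not scene content
    interior = ndimage.binary_erosion(sel, iterations=2)
    if interior.any():
        sel = interior

    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    red_dom = (r > np.maximum(g, b) + red_margin) & sel
    red_fraction = float(red_dom.sum() / sel.sum())

    gray = (0.299 * r + 0.587 * g + 0.114 * b) * 255.0
    lap = ndimage.laplace(gray)
    laplacian_variance = float(lap[sel].var())

    brightness = float(img[sel].mean())
    saturated = float((img[sel].min(axis=-1) > 0.95).mean())
    return FrameQuality(center=center, radius=radius,
                        red_fraction=red_fraction,
                        laplacian_variance=laplacian_variance,
                        mean_brightness=brightness,
                        saturated_fraction=saturated)


def select_frames(frames: Sequence[tuple[object, np.ndarray]],
                  thresholds: FilterThresholds | None = None
                  ) -> tuple[list, list[tuple[object, str]]]:
    """Apply all quality gates; every exclusion carries its first failure.

    frames: sequence of (identifier, image) pairs.
    Returns (kept identifiers, [(identifier, reason), ...]).
    Tests run in a fixed order — mask, brightness (dark), brightness
    (bright/saturated), blur, red — and the first failure is the reason.
    """
    th = thresholds or FilterThresholds()
    kept: list = []
    excluded: list[tuple[object, str]] = []
    for ident, image in frames:
        try:
            circle = fit_circular_mask(image)
        except ValueError:
            excluded.append((ident, "no_field_of_view"))
            continue
        q = frame_quality(image, circle, red_margin=th.red_margin)
        if q.mean_brightness < th.min_brightness:
            excluded.append((ident, "too_dark"))
        elif (q.mean_brightness > th.max_brightness
              or q.saturated_fraction > th.max_saturated_fraction):
            excluded.append((ident, "over_exposed"))
        elif q.laplacian_variance < th.min_laplacian_variance:
            excluded.append((ident, "too_blurry"))
        elif q.red_fraction < th.min_red_fraction:
            excluded.append((ident, "not_red_enough"))
        else:
            kept.append(ident)
    return kept, excluded
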