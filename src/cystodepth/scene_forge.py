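"""Procedural synthetic cystoscopy: bladder-like cavities rendered as RGB-D.

Real bladders are irregular, singular, closed volumes; ground-truth depth
for real cystoscopic video cannot be measured.  This module stands in for a
mesh-based rendering pipeline with a fully procedural one: each cavity is a
star-shaped implicit surface, a radius function rho(direction) of direction
from an interior origin, composed of

* a base radius,
* low-frequency lobed deformation terms (irregular organ shape),
* fractal value-noise displacement (bumpy, wrinkly walls),
* Gaussian-in-angle protrusions into the cavity (polyp-like bodies).

Star-shape guarantees a unique ray/wall intersection from any interior
camera, so depth maps are exact up to the bisection tolerance, and the
undeformed sphere limit is verifiable against the closed-form ray-sphere
solution.

Frames are shaded with two camera-attached conical light sources
(endoscope-style), a Lambert term with inverse-square falloff, a small
specular highlight and a soft wrap term approximating the translucency of
tissue.  Vessel-like texture comes from thresholded ridged value noise.
Post-render augmentations (circular mask, color jitter, rotation,
translation) mirror what is applied to real frames.

All quantities are millimetres unless stated otherwise; every operation is
a pure function of (inputs, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "ConfigurationError", "RenderError",
    "PolypSpec", "SceneSpec", "CameraPose", "RGBDFrame",
    "SceneGenConfig", "PoseConfig", "RenderConfig", "AugmentConfig",
    "DatasetConfig", "FrameRecord", "DatasetManifest",
    "sample_scene_spec", "radial_surface", "sample_camera_pose",
    "render_frame", "augment_frame", "generate_dataset", "partition_dataset",
    "load_frame",
]

DEPTH_PNG_MAX = 60000  # max depth maps to this 16-bit code value


class ConfigurationError(ValueError):
    """A generation config that cannot produce valid scenes."""


class RenderError(RuntimeError):
    """Ray casting failed; indicates an invalid spec/pose or a bug."""


# ---------------------------------------------------------------------------
# Seeded lattice noise (value noise + fBm + ridged variant)
# ---------------------------------------------------------------------------

_MASK32 = np.uint64(0xFFFFFFFF)


def _lattice(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic hash of integer lattice coordinates -> uniform [-1, 1)."""
    h = (ix.astype(np.uint64) * np.uint64(374761393)
         + iy.astype(np.uint64) * np.uint64(668265263)
         + iz.astype(np.uint64) * np.uint64(1274126177)
         + np.uint64(seed % (1 << 31)) * np.uint64(2246822519)) & _MASK32
    h ^= h >> np.uint64(13)
    h = (h * np.uint64(1274126177)) & _MASK32
    h ^= h >> np.uint64(16)
    return h.astype(np.float64) / float(1 << 31) - 1.0


def value_noise(points: np.ndarray, seed: int) -> np.ndarray:
    """Smooth zero-mean lattice noise at float 3-D points, range (-1, 1)."""
    p = np.asarray(points, dtype=np.float64)
    i0 = np.floor(p).astype(np.int64)
    f = p - i0
    w = f * f * f * (f * (f * 6.0 - 15.0) + 10.0)  # quintic fade
    out = np.zeros(p.shape[:-1])
    for dx in (0, 1):
        wx = w[..., 0] if dx else 1.0 - w[..., 0]
        for dy in (0, 1):
            wy = w[..., 1] if dy else 1.0 - w[..., 1]
            for dz in (0, 1):
                wz = w[..., 2] if dz else 1.0 - w[..., 2]
                v = _lattice(i0[..., 0] + dx, i0[..., 1] + dy,
                             i0[..., 2] + dz, seed)
                out += wx * wy * wz * v
    return out


def fbm(points: np.ndarray, octaves: int, seed: int,
        lacunarity: float = 2.0, gain: float = 0.5) -> np.ndarray:
    """Fractal sum of value noise, normalized to (-1, 1)."""
    p = np.asarray(points, dtype=np.float64)
    total = np.zeros(p.shape[:-1])
    amp, freq, norm = 1.0, 1.0, 0.0
    for o in range(octaves):
        total += amp * value_noise(p * freq, seed + 101 * o)
        norm += amp
        amp *= gain
        freq *= lacunarity
    return total / norm


def ridged(points: np.ndarray, octaves: int, seed: int) -> np.ndarray:
    """Ridge field in [0, 1]; values near 1 form thin curvilinear sets."""
    return 1.0 - np.abs(fbm(points, octaves, seed))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolypSpec:
    """A polyp-like protrusion into the cavity at a wall location."""
    direction: tuple[float, float, float]  # unit vector, surface location
    height: float                          # mm, > 0
    footprint_sigma: float                 # radians, angular Gaussian width


@dataclass(frozen=True)
class SceneSpec:
    """Procedural description of one bladder-like cavity."""
    scene_id: str
    base_radius: float                                    # mm
    deform_amplitudes: tuple[tuple[float, float], ...]    # (frequency, amplitude mm)
    perlin_params: tuple[int, float, float]               # octaves, scale, amplitude mm
    polyps: tuple[PolypSpec, ...]
    material: str                                         # "plain" | "textured"
    texture_params: tuple                                 # (base_color, vessel_density,
    #                                                        vessel_contrast, brightness)
    light_params: tuple[float, float, float]              # (cone half-angle deg,
    #                                                        intensity, lateral offset mm)
    noise_seed: int = 0                                   # drives displacement + texture

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ConfigurationError("base_radius must be positive")
        if self.material not in ("plain", "textured"):
            raise ConfigurationError(f"unknown material {self.material!r}")
        for p in self.polyps:
            if p.height <= 0 or p.footprint_sigma <= 0:
                raise ConfigurationError("polyp height and sigma must be positive")
            if p.height > self.base_radius / 2:
                raise ConfigurationError(
                    "polyp height exceeds base_radius/2; surface no longer star-shaped")
        if self.min_radius_bound() <= 0:
            raise ConfigurationError(
                "perturbations can push the wall through the center "
                "(star-shape invariant violated)")

    def min_radius_bound(self) -> float:
        """Conservative lower bound on rho over all directions."""
        neg = sum(abs(a) for _, a in self.deform_amplitudes)
        neg += abs(self.perlin_params[2])
        neg += sum(p.height for p in self.polyps)
        return self.base_radius - neg

    def max_radius_bound(self) -> float:
        pos = sum(abs(a) for _, a in self.deform_amplitudes)
        pos += abs(self.perlin_params[2])
        return self.base_radius + pos


@dataclass(frozen=True)
class CameraPose:
    position: tuple[float, float, float]   # mm, strictly inside the cavity
    view_dir: tuple[float, float, float]   # unit vector
    up: tuple[float, float, float]         # unit vector orthogonal to view_dir
    fov: float                             # degrees, full horizontal angle


@dataclass
class RGBDFrame:
    """One rendered (or ingested) sample: color, metric depth, validity mask."""
    rgb: np.ndarray     # H x W x 3 float in [0, 1]; 0 outside mask
    depth: np.ndarray   # H x W float mm; 0 outside mask
    mask: np.ndarray    # H x W bool, circular field of view
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not np.all(self.depth[self.mask] > 0):
            raise ValueError("masked pixels must carry positive depth")
        if np.any(self.depth[~self.mask] != 0):
            raise ValueError("depth must be 0 outside the mask")
        if np.any(self.rgb[~self.mask] != 0):
            raise ValueError("rgb must be 0 outside the mask")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def _check_range(name: str, rng: tuple[float, float]) -> None:
    if rng[0] > rng[1]:
        raise ConfigurationError(f"range {name} has min > max: {rng}")


@dataclass(frozen=True)
class SceneGenConfig:
    """Sampling ranges for every SceneSpec field.

    Defaults produce cavities 25-40 mm in radius with gentle lobes, a bumpy
    wall and 0-2 polyps — the scale of a moderately filled human bladder.
    """
    base_radius_range: tuple[float, float] = (25.0, 40.0)
    n_deform_terms_range: tuple[int, int] = (1, 2)
    deform_frequency_range: tuple[int, int] = (2, 5)
    deform_amplitude_range: tuple[float, float] = (0.5, 2.0)
    perlin_octaves_range: tuple[int, int] = (2, 4)
    perlin_scale_range: tuple[float, float] = (1.5, 3.0)
    perlin_amplitude_range: tuple[float, float] = (0.4, 1.5)
    n_polyps_range: tuple[int, int] = (0, 2)
    polyp_height_range: tuple[float, float] = (2.0, 5.0)
    polyp_sigma_range: tuple[float, float] = (0.15, 0.4)
    material: str = "textured"
    base_color_low: tuple[float, float, float] = (0.62, 0.28, 0.26)
    base_color_high: tuple[float, float, float] = (0.85, 0.48, 0.42)
    vessel_density_range: tuple[float, float] = (1.5, 3.0)
    vessel_contrast_range: tuple[float, float] = (0.3, 0.7)
    brightness_scale_range: tuple[float, float] = (0.75, 1.25)
    cone_half_angle_range: tuple[float, float] = (50.0, 70.0)
    intensity_range: tuple[float, float] = (50.0, 130.0)
    lateral_offset: float = 2.0

    def validate(self) -> None:
        for name in ("base_radius_range", "n_deform_terms_range",
                     "deform_frequency_range", "deform_amplitude_range",
                     "perlin_octaves_range", "perlin_scale_range",
                     "perlin_amplitude_range", "n_polyps_range",
                     "polyp_height_range", "polyp_sigma_range",
                     "vessel_density_range", "vessel_contrast_range",
                     "brightness_scale_range", "cone_half_angle_range",
                     "intensity_range"):
            _check_range(name, getattr(self, name))
        if not (0.5 <= self.brightness_scale_range[0]
                and self.brightness_scale_range[1] <= 1.5):
            raise ConfigurationError("brightness_scale must stay within [0.5, 1.5]")
        # worst case: every perturbation takes its maximum magnitude at once
        worst = (self.n_deform_terms_range[1] * self.deform_amplitude_range[1]
                 + self.perlin_amplitude_range[1]
                 + self.n_polyps_range[1] * self.polyp_height_range[1])
        if self.base_radius_range[0] - worst <= 0:
            raise ConfigurationError(
                "amplitude ranges can violate the star-shape invariant "
                f"(worst-case perturbation {worst:.2f} >= min base radius "
                f"{self.base_radius_range[0]:.2f})")
        if self.polyp_height_range[1] > self.base_radius_range[0] / 2:
            raise ConfigurationError("polyp height range exceeds base_radius/2")


@dataclass(frozen=True)
class PoseConfig:
    wall_distance_range: tuple[float, float] = (5.0, 25.0)  # mm from the wall
    max_view_deviation: float = 30.0                        # degrees
    fov: float = 70.0                                       # degrees
    min_center_clearance: float = 1.0                       # mm kept off the wall
    max_retries: int = 100

    def validate(self) -> None:
        _check_range("wall_distance_range", self.wall_distance_range)
        if self.max_view_deviation < 0:
            raise ConfigurationError("max_view_deviation must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    image_size: int = 256
    mask_radius_fraction: float = 0.95  # of the half image width
    bisect_iters: int = 45
    specular_strength: float = 0.08
    specular_power: float = 30.0
    wrap_weight: float = 0.25           # soft translucency approximation
    wrap_factor: float = 0.3
    cone_floor: float = 0.05            # residual light outside the cone


@dataclass(frozen=True)
class AugmentConfig:
    brightness_jitter: float = 0.2
    contrast_jitter: float = 0.2
    channel_gain_jitter: float = 0.1
    translation_range: int = 10                      # pixels
    rotation_range: tuple[float, float] = (0.0, 360.0)  # degrees


@dataclass(frozen=True)
class DatasetConfig:
    n_models: int = 2
    images_per_model_per_material: int = 3
    out_dir: str = "dataset"
    image_size: int = 64
    n_val_models: int = 0
    n_test_models: int = 0
    scene: SceneGenConfig = field(default_factory=SceneGenConfig)
    pose: PoseConfig = field(default_factory=PoseConfig)
    render: RenderConfig | None = None
    augment: AugmentConfig | None = None   # None: no post-render augmentation
    materials: tuple[str, ...] = ("plain", "textured")


# ---------------------------------------------------------------------------
# Scene sampling and the implicit surface
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def _random_unit(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    v = rng.normal(size=(3,) if n is None else (n, 3))
    return _unit(v)


def sample_scene_spec(config: SceneGenConfig, seed: int,
                      scene_id: str | None = None) -> SceneSpec:
    """Draw one cavity description; identical (config, seed) -> identical spec."""
    config.validate()
    rng = np.random.default_rng(seed)
    base_radius = rng.uniform(*config.base_radius_range)
    n_terms = int(rng.integers(config.n_deform_terms_range[0],
                               config.n_deform_terms_range[1] + 1))
    deform = tuple(
        (float(rng.integers(config.deform_frequency_range[0],
                            config.deform_frequency_range[1] + 1)),
         float(rng.uniform(*config.deform_amplitude_range)))
        for _ in range(n_terms))
    perlin = (int(rng.integers(config.perlin_octaves_range[0],
                               config.perlin_octaves_range[1] + 1)),
              float(rng.uniform(*config.perlin_scale_range)),
              float(rng.uniform(*config.perlin_amplitude_range)))
    n_polyps = int(rng.integers(config.n_polyps_range[0],
                                config.n_polyps_range[1] + 1))
    polyps = tuple(
        PolypSpec(direction=tuple(_random_unit(rng)),
                  height=float(rng.uniform(*config.polyp_height_range)),
                  footprint_sigma=float(rng.uniform(*config.polyp_sigma_range)))
        for _ in range(n_polyps))
    base_color = tuple(float(rng.uniform(lo, hi)) for lo, hi in
                       zip(config.base_color_low, config.base_color_high))
    texture = (base_color,
               float(rng.uniform(*config.vessel_density_range)),
               float(rng.uniform(*config.vessel_contrast_range)),
               float(rng.uniform(*config.brightness_scale_range)))
    light = (float(rng.uniform(*config.cone_half_angle_range)),
             float(rng.uniform(*config.intensity_range)),
             float(config.lateral_offset))
    return SceneSpec(
        scene_id=scene_id or f"scene_{seed:08d}",
        base_radius=float(base_radius),
        deform_amplitudes=deform,
        perlin_params=perlin,
        polyps=polyps,
        material=config.material,
        texture_params=texture,
        light_params=light,
        noise_seed=int(rng.integers(0, 2 ** 31)),
    )


def radial_surface(spec: SceneSpec, direction: np.ndarray) -> np.ndarray | float:
    """rho(direction): wall distance from the cavity center, mm.

    direction: unit 3-vector or (..., 3) array of unit vectors.
    """
    d = np.asarray(direction, dtype=np.float64)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    norms = np.linalg.norm(d, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero direction vector")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("direction vectors must be unit length")
    rho = np.full(d.shape[:-1], spec.base_radius)

    if spec.deform_amplitudes:
        phi = np.arctan2(d[..., 1], d[..., 0])
        sin_theta = np.sqrt(np.clip(1.0 - d[..., 2] ** 2, 0.0, 1.0))
        for k, (freq, amp) in enumerate(spec.deform_amplitudes):
            phase = 2.0 * math.pi * _lattice(
                np.array(k), np.array(0), np.array(0), spec.noise_seed + 7)
            rho += amp * np.cos(freq * phi + float(phase)) * sin_theta

    octaves, scale, amplitude = spec.perlin_params
    if amplitude != 0.0:
        rho += amplitude * fbm(d * scale, octaves, spec.noise_seed)

    for p in spec.polyps:
        cosang = np.clip(d @ np.asarray(p.direction), -1.0, 1.0)
        ang = np.arccos(cosang)
        rho -= p.height * np.exp(-0.5 * (ang / p.footprint_sigma) ** 2)

    if np.any(rho <= 0):
        raise RenderError("radial surface crossed the center; invalid spec")
    return float(rho[0]) if single else rho.reshape(np.asarray(direction).shape[:-1])


def _orthonormal_to(v: np.ndarray) -> np.ndarray:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, helper))


def sample_camera_pose(spec: SceneSpec, pose_config: PoseConfig,
                       seed: int) -> CameraPose:
    """Place the camera at a random wall distance along a random center ray."""
    pose_config.validate()
    rng = np.random.default_rng(seed)
    for _ in range(pose_config.max_retries):
        v = _random_unit(rng)
        rho_v = float(radial_surface(spec, v))
        d = rng.uniform(*pose_config.wall_distance_range)
        t = rho_v - d
        if t < 0.0:  # requested wall distance exceeds the cavity along v
            continue
        position = t * v
        # t == 0 places the camera at the center: |position| = 0 < rho holds
        max_dev = math.radians(pose_config.max_view_deviation)
        dev = rng.uniform(0.0, max_dev)
        azim = rng.uniform(0.0, 2.0 * math.pi)
        e1 = _orthonormal_to(v)
        e2 = np.cross(v, e1)
        view_dir = (math.cos(dev) * v
                    + math.sin(dev) * (math.cos(azim) * e1 + math.sin(azim) * e2))
        view_dir = _unit(view_dir)
        up = _orthonormal_to(view_dir)
        return CameraPose(position=tuple(position), view_dir=tuple(view_dir),
                          up=tuple(up), fov=pose_config.fov)
    raise ConfigurationError(
        "could not place a camera: wall-distance range exceeds the cavity size")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ray_march_and_bisect(spec: SceneSpec, origin: np.ndarray,
                          dirs: np.ndarray, config: RenderConfig) -> np.ndarray:
    """Hit distance t per ray for f(t) = |p(t)| - rho(p(t)/|p(t)|) = 0."""
    n = dirs.shape[0]
    t_max = 2.0 * spec.max_radius_bound() + float(np.linalg.norm(origin))

    def f(t, u):
        p = origin[None, :] + t[:, None] * u
        r = np.linalg.norm(p, axis=-1)
        d = np.where(r[:, None] > 1e-9, p / np.maximum(r, 1e-9)[:, None],
                     u)  # a point at the exact center: rho along the ray
        return r - radial_surface(spec, d)

    step = max(spec.min_radius_bound() * 0.5, 0.5)
    t_lo = np.zeros(n)
    t_hi = np.full(n, step)
    unresolved = np.ones(n, dtype=bool)
    for _ in range(int(math.ceil(t_max / step)) + 2):
        vals = f(t_hi[unresolved], dirs[unresolved])
        newly = vals > 0
        idx = np.flatnonzero(unresolved)
        unresolved[idx[newly]] = False
        still = idx[~newly]
        t_lo[still] = t_hi[still]
        t_hi[still] += step
        if not unresolved.any():
            break
    if unresolved.any():
        raise RenderError("a ray found no wall intersection; invalid spec/pose")

    for _ in range(config.bisect_iters):
        mid = 0.5 * (t_lo + t_hi)
        inside = f(mid, dirs) < 0
        t_lo = np.where(inside, mid, t_lo)
        t_hi = np.where(inside, t_hi, mid)
    return 0.5 * (t_lo + t_hi)


def _surface_normal(spec: SceneSpec, points: np.ndarray,
                    eps: float = 1e-3) -> np.ndarray:
    """Inward normal of F(p) = |p| - rho(p/|p|) by central differences."""
    grad = np.zeros_like(points)
    for axis in range(3):
        offset = np.zeros(3)
        offset[axis] = eps

        def F(p):
            r = np.linalg.norm(p, axis=-1)
            return r - radial_surface(spec, p / r[:, None])

        grad[:, axis] = (F(points + offset) - F(points - offset)) / (2 * eps)
    return -_unit(grad)  # inward: toward the cavity interior


def _albedo(spec: SceneSpec, hit_dirs: np.ndarray) -> np.ndarray:
    base_color, vessel_density, vessel_contrast, brightness = spec.texture_params
    albedo = np.broadcast_to(np.asarray(base_color), hit_dirs.shape).copy()
    if spec.material == "textured":
        seed = spec.noise_seed + 977
        ridge = ridged(hit_dirs * vessel_density * 4.0, 3, seed)
        stroke = np.clip((ridge - 0.90) / 0.08, 0.0, 1.0)  # thin curvilinear
        vessel_color = np.array([0.45, 0.06, 0.06])
        mix = (stroke * vessel_contrast)[..., None]
        albedo = albedo * (1.0 - mix) + vessel_color * mix
        mottle = 1.0 + 0.10 * fbm(hit_dirs * 2.0, 2, seed + 5)
        albedo = albedo * mottle[..., None]
        albedo = albedo * brightness
    return np.clip(albedo, 0.0, 1.0)


def render_frame(spec: SceneSpec, pose: CameraPose,
                 render_config: RenderConfig | None = None) -> RGBDFrame:
    """Ray-cast one RGB-D frame from an interior camera pose."""
    cfg = render_config or RenderConfig()
    H = W = cfg.image_size

    origin = np.asarray(pose.position, dtype=np.float64)
    fwd = _unit(np.asarray(pose.view_dir, dtype=np.float64))
    up = _unit(np.asarray(pose.up, dtype=np.float64))
    right = np.cross(fwd, up)

    jj, ii = np.meshgrid(np.arange(W), np.arange(H))
    x = (jj + 0.5 - W / 2) / (W / 2)
    y = (ii + 0.5 - H / 2) / (H / 2)
    mask = (x ** 2 + y ** 2) <= cfg.mask_radius_fraction ** 2

    half_tan = math.tan(math.radians(pose.fov) / 2)
    dirs = (fwd[None, :]
            + (x[mask] * half_tan)[:, None] * right[None, :]
            - (y[mask] * half_tan)[:, None] * up[None, :])
    dirs = _unit(dirs)

    t_hit = _ray_march_and_bisect(spec, origin, dirs, cfg)
    hits = origin[None, :] + t_hit[:, None] * dirs
    hit_r = np.linalg.norm(hits, axis=-1)
    hit_dirs = hits / hit_r[:, None]
    normals = _surface_normal(spec, hits)
    albedo = _albedo(spec, hit_dirs)

    cone_half_deg, intensity, lateral_offset = spec.light_params
    cos_half = math.cos(math.radians(cone_half_deg))
    shade = np.zeros_like(albedo)
    for side in (-1.0, 1.0):
        light_pos = origin + side * lateral_offset * right
        to_surf = hits - light_pos[None, :]
        dist2 = np.sum(to_surf ** 2, axis=-1)
        wl = to_surf / np.sqrt(dist2)[:, None]
        cos_axis = wl @ fwd
        cone = cfg.cone_floor + (1.0 - cfg.cone_floor) * np.clip(
            (cos_axis - cos_half) / (1.0 - cos_half), 0.0, 1.0)
        ndotl = np.sum(normals * (-wl), axis=-1)
        lambert = np.maximum(ndotl, 0.0)
        wrap = np.clip((ndotl + cfg.wrap_factor) / (1.0 + cfg.wrap_factor),
                       0.0, 1.0)
        diffuse = lambert + cfg.wrap_weight * wrap
        shade += albedo * (intensity * cone * diffuse / dist2)[:, None]
        # small specular highlight, independent of light intensity scaling
        refl = _unit(wl + 2.0 * ndotl[:, None] * normals)
        spec_term = np.maximum(np.sum(refl * (-dirs), axis=-1), 0.0) ** cfg.specular_power
        shade += cfg.specular_strength * (cone * spec_term)[:, None]

    rgb = np.zeros((H, W, 3))
    rgb[mask] = np.clip(shade, 0.0, 1.0)
    depth = np.zeros((H, W))
    depth[mask] = t_hit

    frame = RGBDFrame(rgb=rgb, depth=depth, mask=mask, meta={
        "scene_id": spec.scene_id,
        "material": spec.material,
        "pose": {"position": list(pose.position),
                 "view_dir": list(pose.view_dir),
                 "up": list(pose.up), "fov": pose.fov},
        "augmentations": [],
    })
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# Post-render augmentation
# ---------------------------------------------------------------------------

def _rigid_resample(img: np.ndarray, angle_deg: float, shift: tuple[float, float],
                    order: int) -> np.ndarray:
    """Rotate about the image center then translate by (dy, dx) pixels."""
    H, W = img.shape[:2]
    c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    inv = rot.T  # inverse rotation for the output -> input mapping
    offset = c - inv @ (c + np.asarray(shift))
    if img.ndim == 2:
        return ndimage.affine_transform(img, inv, offset=offset, order=order,
                                        mode="constant", cval=0.0, prefilter=False)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.affine_transform(img[..., ch], inv, offset=offset,
                                                order=order, mode="constant",
                                                cval=0.0, prefilter=False)
    return out


def augment_frame(frame: RGBDFrame, aug_config: AugmentConfig,
                  seed: int) -> RGBDFrame:
    """Photometric jitter on color plus a rigid rotation+translation on all
    channels; depth and mask are resampled by nearest neighbor so no values
    blend across the circular mask edge."""
    cfg = aug_config
    rng = np.random.default_rng(seed)

    b = float(rng.uniform(1.0 - cfg.brightness_jitter, 1.0 + cfg.brightness_jitter))
    cjit = float(rng.uniform(1.0 - cfg.contrast_jitter, 1.0 + cfg.contrast_jitter))
    gains = rng.uniform(1.0 - cfg.channel_gain_jitter,
                        1.0 + cfg.channel_gain_jitter, size=3)
    angle = float(rng.uniform(*cfg.rotation_range))
    shift = (int(rng.integers(-cfg.translation_range, cfg.translation_range + 1))
             if cfg.translation_range else 0,
             int(rng.integers(-cfg.translation_range, cfg.translation_range + 1))
             if cfg.translation_range else 0)

    rgb = frame.rgb.copy()
    inside = frame.mask
    if not (b == 1.0 and cjit == 1.0 and np.all(gains == 1.0)):
        mean = rgb[inside].mean() if inside.any() else 0.0
        rgb[inside] = (rgb[inside] - mean) * cjit + mean
        rgb[inside] = rgb[inside] * b * gains[None, :]
        rgb = np.clip(rgb, 0.0, 1.0)
        rgb[~inside] = 0.0

    identity = angle == 0.0 and shift == (0, 0)
    if identity:
        new_rgb, new_depth = rgb, frame.depth.copy()
        new_mask = frame.mask.copy()
    else:
        new_mask = _rigid_resample(frame.mask.astype(np.float64), angle, shift,
                                   order=0) > 0.5
        if not new_mask.any():
            raise ValueError("augmentation moved the entire mask out of frame")
        new_depth = _rigid_resample(frame.depth, angle, shift, order=0)
        new_rgb = _rigid_resample(rgb, angle, shift, order=1)
        new_rgb = np.clip(new_rgb, 0.0, 1.0)
        new_rgb[~new_mask] = 0.0
        new_depth[~new_mask] = 0.0
        # nearest-neighbor stragglers just inside the resampled mask edge
        bad = new_mask & (new_depth <= 0)
        if bad.any():
            new_mask = new_mask & ~bad
            new_rgb[bad] = 0.0

    meta = dict(frame.meta)
    meta["augmentations"] = list(meta.get("augmentations", [])) + [{
        "brightness": b, "contrast": cjit, "gains": gains.tolist(),
        "rotation_deg": angle, "translation_px": list(shift), "seed": int(seed),
    }]
    out = RGBDFrame(rgb=new_rgb, depth=new_depth, mask=new_mask, meta=meta)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Dataset generation, I/O, partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameRecord:
    scene_id: str
    material: str
    index: int
    rgb_path: str
    depth_path: str
    mask_path: str
    meta_path: str


@dataclass
class DatasetManifest:
    root: str
    depth_scale: float              # mm per 16-bit code value
    frames: list[FrameRecord]
    split: dict[str, str]           # scene_id -> train | val | test

    def frames_for(self, split: str) -> list[FrameRecord]:
        return [f for f in self.frames if self.split.get(f.scene_id) == split]

    def scene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.frames:
            seen.setdefault(f.scene_id)
        return list(seen)

    def to_dict(self) -> dict:
        return {"depth_scale": self.depth_scale,
                "frames": [dataclasses.asdict(f) for f in self.frames],
                "split": self.split}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "DatasetManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(root=os.path.dirname(os.path.abspath(path)),
                   depth_scale=d["depth_scale"],
                   frames=[FrameRecord(**f) for f in d["frames"]],
                   split=d["split"])


def write_frame(frame: RGBDFrame, root: str, rec: FrameRecord,
                depth_scale: float) -> None:
    os.makedirs(os.path.dirname(os.path.join(root, rec.rgb_path)), exist_ok=True)
    iio.imwrite(os.path.join(root, rec.rgb_path),
                (np.clip(frame.rgb, 0, 1) * 255).round().astype(np.uint8))
    code = np.clip(np.round(frame.depth / depth_scale), 0, 65535).astype(np.uint16)
    iio.imwrite(os.path.join(root, rec.depth_path), code)
    iio.imwrite(os.path.join(root, rec.mask_path),
                (frame.mask.astype(np.uint8) * 255))
    with open(os.path.join(root, rec.meta_path), "w") as fh:
        json.dump({"depth_scale": depth_scale, **frame.meta}, fh,
                  indent=1, sort_keys=True)


def load_frame(manifest: DatasetManifest, rec: FrameRecord) -> RGBDFrame:
    rgb = iio.imread(os.path.join(manifest.root, rec.rgb_path)
                     ).astype(np.float64) / 255.0
    code = iio.imread(os.path.join(manifest.root, rec.depth_path))
    depth = code.astype(np.float64) * manifest.depth_scale
    mask = iio.imread(os.path.join(manifest.root, rec.mask_path)) > 127
    with open(os.path.join(manifest.root, rec.meta_path)) as fh:
        meta = json.load(fh)
    depth[~mask] = 0.0
    rgb[~mask] = 0.0
    return RGBDFrame(rgb=rgb, depth=depth, mask=mask, meta=meta)


def partition_dataset(n_models: int, images_per_model: int,
                      n_val_models: int, n_test_models: int
                      ) -> tuple[tuple[int, int, int], dict[int, str]]:
    """Model-level split: no model contributes frames to two splits.

    Returns ((train_count, val_count, test_count), {model_index: split}).
    """
    if n_val_models + n_test_models >= n_models:
        raise ValueError("n_val_models + n_test_models must be < n_models")
    if min(n_models, images_per_model) <= 0 or min(n_val_models, n_test_models) < 0:
        raise ValueError("counts must be positive (splits non-negative)")
    n_train = n_models - n_val_models - n_test_models
    assignment: dict[int, str] = {}
    for m in range(n_models):
        if m < n_train:
            assignment[m] = "train"
        elif m < n_train + n_val_models:
            assignment[m] = "val"
        else:
            assignment[m] = "test"
    counts = (n_train * images_per_model,
              n_val_models * images_per_model,
              n_test_models * images_per_model)
    return counts, assignment


def generate_dataset(dataset_config: DatasetConfig, seed: int) -> DatasetManifest:
    """Render the full synthetic dataset to disk and return its manifest.

    For each procedural model, `images_per_model_per_material` frames are
    rendered under every configured material (by default both plain and
    textured: same geometry and poses, different shading).
    """
    cfg = dataset_config
    render_cfg = cfg.render or RenderConfig(image_size=cfg.image_size)
    os.makedirs(cfg.out_dir, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    model_seeds = root_ss.spawn(cfg.n_models)

    # depth code scale fixed by the config's worst-case geometry so frames
    # can stream to disk; max representable depth -> DEPTH_PNG_MAX
    max_rho = (cfg.scene.base_radius_range[1]
               + cfg.scene.n_deform_terms_range[1] * cfg.scene.deform_amplitude_range[1]
               + cfg.scene.perlin_amplitude_range[1])
    depth_scale = (2.0 * max_rho) / DEPTH_PNG_MAX

    _, assignment = partition_dataset(
        cfg.n_models, len(cfg.materials) * cfg.images_per_model_per_material,
        cfg.n_val_models, cfg.n_test_models)

    frames: list[FrameRecord] = []
    split: dict[str, str] = {}
    for m, mseed in enumerate(model_seeds):
        child = np.random.default_rng(mseed)
        spec_seed = int(child.integers(0, 2 ** 31))
        scene_id = f"scene_{m:03d}"
        base_spec = sample_scene_spec(cfg.scene, spec_seed, scene_id=scene_id)
        split[scene_id] = assignment[m]
        for material in cfg.materials:
            spec = dataclasses.replace(base_spec, material=material)
            for k in range(cfg.images_per_model_per_material):
                pose_seed = int(child.integers(0, 2 ** 31))
                pose = sample_camera_pose(spec, cfg.pose, pose_seed)
                try:
                    frame = render_frame(spec, pose, render_cfg)
                    if cfg.augment is not None:
                        aug_seed = int(child.integers(0, 2 ** 31))
                        frame = augment_frame(frame, cfg.augment, aug_seed)
                except (RenderError, ValueError) as exc:
                    raise RenderError(
                        f"render failed for scene {scene_id}, material "
                        f"{material}, frame {k}: {exc}") from exc
                rec = FrameRecord(
                    scene_id=scene_id, material=material, index=k,
                    rgb_path=f"{scene_id}/{material}/rgb_{k:06d}.png",
                    depth_path=f"{scene_id}/{material}/depth_{k:06d}.png",
                    mask_path=f"{scene_id}/{material}/mask_{k:06d}.png",
                    meta_path=f"{scene_id}/{material}/meta_{k:06d}.json")
                write_frame(frame, cfg.out_dir, rec, depth_scale)
                frames.append(rec)

    manifest = DatasetManifest(root=os.path.abspath(cfg.out_dir),
                               depth_scale=depth_scale,
                               frames=frames, split=split)
    manifest.save(os.path.join(cfg.out_dir, "manifest.json"))
    return manifest
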