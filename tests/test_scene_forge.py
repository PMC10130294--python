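"""Procedural scene sampling, the implicit surface, rendering, augmentation,
dataset generation and the model-level partition."""

import dataclasses
import json

import numpy as np
import pytest

from cystodepth import scene_forge as sf

IDENTITY_AUG = sf.AugmentConfig(brightness_jitter=0.0, contrast_jitter=0.0,
                                channel_gain_jitter=0.0, translation_range=0,
                                rotation_range=(0.0, 0.0))


# ---------------------------------------------------------------------------
# sample_scene_spec
# ---------------------------------------------------------------------------

class TestSampleSceneSpec:
    def test_deterministic_given_seed(self):
        cfg = sf.SceneGenConfig()
        assert sf.sample_scene_spec(cfg, 0) == sf.sample_scene_spec(cfg, 0)
        assert sf.sample_scene_spec(cfg, 0) != sf.sample_scene_spec(cfg, 1)

    def test_zero_polyp_range_yields_no_polyps(self):
        cfg = dataclasses.replace(sf.SceneGenConfig(), n_polyps_range=(0, 0))
        assert sf.sample_scene_spec(cfg, 3).polyps == ()

    def test_star_shape_violating_ranges_rejected(self):
        cfg = dataclasses.replace(
            sf.SceneGenConfig(), base_radius_range=(10.0, 12.0),
            deform_amplitude_range=(4.0, 6.0), n_deform_terms_range=(2, 2))
        with pytest.raises(sf.ConfigurationError):
            sf.sample_scene_spec(cfg, 0)

    def test_inverted_range_rejected(self):
        cfg = dataclasses.replace(sf.SceneGenConfig(),
                                  base_radius_range=(40.0, 25.0))
        with pytest.raises(sf.ConfigurationError):
            sf.sample_scene_spec(cfg, 0)

    def test_sampled_specs_satisfy_invariants(self):
        cfg = sf.SceneGenConfig()
        for seed in range(20):
            spec = sf.sample_scene_spec(cfg, seed)
            assert spec.min_radius_bound() > 0
            for p in spec.polyps:
                assert 0 < p.height <= spec.base_radius / 2
                assert abs(np.linalg.norm(p.direction) - 1) < 1e-9


# ---------------------------------------------------------------------------
# radial_surface
# ---------------------------------------------------------------------------

class TestRadialSurface:
    def test_sphere_limit(self, sphere_spec):
        dirs = np.random.default_rng(0).normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(sf.radial_surface(sphere_spec, dirs), 30.0)

    def test_polyp_apex_reduces_radius_by_height(self, sphere_spec):
        spec = dataclasses.replace(
            sphere_spec,
            polyps=(sf.PolypSpec(direction=(0.0, 0.0, 1.0), height=5.0,
                                 footprint_sigma=0.2),))
        assert sf.radial_surface(spec, np.array([0.0, 0.0, 1.0])) \
            == pytest.approx(25.0)
        # far from the bump the sphere is untouched
        assert sf.radial_surface(spec, np.array([0.0, 0.0, -1.0])) \
            == pytest.approx(30.0, abs=1e-6)

    def test_zero_mean_perlin_monte_carlo(self, sphere_spec):
        spec = dataclasses.replace(sphere_spec, perlin_params=(3, 2.0, 1.5),
                                   noise_seed=42)
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(10_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mean = sf.radial_surface(spec, dirs).mean()
        assert abs(mean - 30.0) / 30.0 < 0.02

    def test_zero_vector_rejected(self, sphere_spec):
        with pytest.raises(ValueError):
            sf.radial_surface(sphere_spec, np.zeros(3))


# ---------------------------------------------------------------------------
# sample_camera_pose
# ---------------------------------------------------------------------------

class TestSampleCameraPose:
    def test_positions_strictly_inside(self, sampled_spec):
        cfg = sf.PoseConfig()
        for seed in range(200):
            pose = sf.sample_camera_pose(sampled_spec, cfg, seed)
            p = np.asarray(pose.position)
            r = np.linalg.norm(p)
            if r > 0:
                assert r < sf.radial_surface(sampled_spec, p / r)
            v = np.asarray(pose.view_dir)
            assert abs(np.linalg.norm(v) - 1) < 1e-9
            assert abs(np.dot(v, pose.up)) < 1e-9

    def test_zero_deviation_aligns_view_with_center_ray(self, sampled_spec):
        cfg = dataclasses.replace(sf.PoseConfig(), max_view_deviation=0.0)
        pose = sf.sample_camera_pose(sampled_spec, cfg, seed=4)
        p = np.asarray(pose.position)
        v = np.asarray(pose.view_dir)
        assert np.allclose(np.cross(p / np.linalg.norm(p), v), 0.0, atol=1e-9)

    def test_view_deviation_bounded(self, sampled_spec):
        cfg = sf.PoseConfig()
        for seed in range(100):
            pose = sf.sample_camera_pose(sampled_spec, cfg, seed)
            p = np.asarray(pose.position)
            r = np.linalg.norm(p)
            if r == 0:
                continue
            cosang = np.dot(p / r, pose.view_dir)
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                <= cfg.max_view_deviation + 1e-6

    def test_deterministic(self, sampled_spec):
        cfg = sf.PoseConfig()
        assert sf.sample_camera_pose(sampled_spec, cfg, 7) \
            == sf.sample_camera_pose(sampled_spec, cfg, 7)

    def test_impossible_wall_distance_errors(self, sphere_spec):
        cfg = dataclasses.replace(sf.PoseConfig(),
                                  wall_distance_range=(100.0, 200.0))
        with pytest.raises(sf.ConfigurationError):
            sf.sample_camera_pose(sphere_spec, cfg, 0)


# ---------------------------------------------------------------------------
# render_frame
# ---------------------------------------------------------------------------

class TestRenderFrame:
    def test_center_camera_sees_constant_radius(self, sphere_spec, center_pose):
        fr = sf.render_frame(sphere_spec, center_pose,
                             sf.RenderConfig(image_size=64))
        d = fr.depth[fr.mask]
        assert np.all(np.abs(d - 30.0) < 0.01)

    def test_offset_camera_central_pixel_matches_ray_sphere(self, sphere_spec):
        pose = sf.CameraPose(position=(0.0, 0.0, 10.0),
                             view_dir=(0.0, 0.0, 1.0),
                             up=(0.0, 1.0, 0.0), fov=70.0)
        fr = sf.render_frame(sphere_spec, pose, sf.RenderConfig(image_size=64))
        # camera 10 mm from the center looking outward: wall at 30 - 10 = 20
        assert fr.depth[32, 32] == pytest.approx(20.0, abs=0.05)

    def test_frame_invariants(self, rendered_frame):
        rendered_frame.validate()
        assert rendered_frame.rgb.min() >= 0 and rendered_frame.rgb.max() <= 1

    def test_doubling_light_intensity_monotone(self, sampled_spec):
        pose = sf.sample_camera_pose(sampled_spec, sf.PoseConfig(), seed=9)
        cfg = sf.RenderConfig(image_size=32)
        lp = sampled_spec.light_params
        bright = dataclasses.replace(
            sampled_spec, light_params=(lp[0], 2 * lp[1], lp[2]))
        a = sf.render_frame(sampled_spec, pose, cfg)
        b = sf.render_frame(bright, pose, cfg)
        assert np.all(b.rgb[a.mask] >= a.rgb[a.mask] - 1e-12)
        unclipped = a.mask & (b.rgb < 1.0 - 1e-9).all(axis=-1) \
            & (a.rgb > 0).any(axis=-1)
        assert np.all(b.rgb[unclipped].sum(-1) > a.rgb[unclipped].sum(-1))

    def test_bisection_residual_below_tolerance(self, sampled_spec):
        pose = sf.sample_camera_pose(sampled_spec, sf.PoseConfig(), seed=2)
        fr = sf.render_frame(sampled_spec, pose, sf.RenderConfig(image_size=32))
        origin = np.asarray(pose.position)
        # recompute |f(t)| at the returned depths for a sample of pixels
        ys, xs = np.nonzero(fr.mask)
        sel = slice(0, len(ys), 37)
        fwd = np.asarray(pose.view_dir)
        up = np.asarray(pose.up)
        right = np.cross(fwd, up)
        H = W = 32
        half_tan = np.tan(np.radians(pose.fov) / 2)
        x = (xs[sel] + 0.5 - W / 2) / (W / 2)
        y = (ys[sel] + 0.5 - H / 2) / (H / 2)
        dirs = fwd + (x * half_tan)[:, None] * right - (y * half_tan)[:, None] * up
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        t = fr.depth[ys[sel], xs[sel]]
        p = origin + t[:, None] * dirs
        r = np.linalg.norm(p, axis=1)
        resid = np.abs(r - sf.radial_surface(sampled_spec, p / r[:, None]))
        assert np.max(resid) < 1e-3

    def test_depth_within_geometric_bounds(self, rendered_frame, sampled_spec):
        d = rendered_frame.depth[rendered_frame.mask]
        assert d.min() > 0
        assert d.max() <= 2 * sampled_spec.max_radius_bound()


# ---------------------------------------------------------------------------
# augment_frame
# ---------------------------------------------------------------------------

class TestAugmentFrame:
    def test_identity_config_is_noop(self, rendered_frame):
        out = sf.augment_frame(rendered_frame, IDENTITY_AUG, seed=0)
        assert np.array_equal(out.rgb, rendered_frame.rgb)
        assert np.array_equal(out.depth, rendered_frame.depth)
        assert np.array_equal(out.mask, rendered_frame.mask)

    def test_rotation_90_plus_270_restores_mask(self, rendered_frame):
        r90 = dataclasses.replace(IDENTITY_AUG, rotation_range=(90.0, 90.0))
        r270 = dataclasses.replace(IDENTITY_AUG, rotation_range=(270.0, 270.0))
        once = sf.augment_frame(rendered_frame, r90, seed=1)
        back = sf.augment_frame(once, r270, seed=2)
        assert np.array_equal(back.mask, rendered_frame.mask)
        assert np.array_equal(back.depth, rendered_frame.depth)

    @pytest.mark.parametrize("angle", [90.0, 180.0, 270.0])
    def test_right_angle_rotation_permutes_depths(self, rendered_frame, angle):
        cfg = dataclasses.replace(IDENTITY_AUG, rotation_range=(angle, angle))
        out = sf.augment_frame(rendered_frame, cfg, seed=0)
        assert np.array_equal(np.sort(out.depth[out.depth > 0]),
                              np.sort(rendered_frame.depth[
                                  rendered_frame.depth > 0]))

    def test_random_augmentation_preserves_invariants(self, rendered_frame):
        for seed in range(5):
            out = sf.augment_frame(rendered_frame, sf.AugmentConfig(), seed)
            out.validate()
            assert out.meta["augmentations"], "meta must record parameters"

    def test_translation_off_frame_errors(self, rendered_frame):
        # a 500 px translation range on a 64 px frame will, for some seed,
        # push the whole mask out of view; that draw must raise
        far = sf.AugmentConfig(brightness_jitter=0, contrast_jitter=0,
                               channel_gain_jitter=0, translation_range=500,
                               rotation_range=(0.0, 0.0))
        with pytest.raises(ValueError, match="mask"):
            for seed in range(100):
                sf.augment_frame(rendered_frame, far, seed)


# ---------------------------------------------------------------------------
# generate_dataset / partition_dataset
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_manifest_counts_and_roundtrip(self, tmp_path):
        cfg = sf.DatasetConfig(n_models=2, images_per_model_per_material=3,
                               out_dir=str(tmp_path / "ds"), image_size=32)
        manifest = sf.generate_dataset(cfg, seed=1)
        assert len(manifest.frames) == 12          # 2 models x 2 materials x 3
        assert len(manifest.scene_ids()) == 2
        loaded = sf.DatasetManifest.load(str(tmp_path / "ds" / "manifest.json"))
        assert loaded.to_dict() == manifest.to_dict()
        # depth PNG round-trip within one 16-bit quantization step
        rec = manifest.frames[0]
        fr = sf.load_frame(manifest, rec)
        fr.validate()
        assert fr.depth[fr.mask].min() > 0
        with open(tmp_path / "ds" / rec.meta_path) as fh:
            meta = json.load(fh)
        assert meta["depth_scale"] == manifest.depth_scale

    def test_depth_quantization_error_bounded(self, tmp_path, sampled_spec):
        pose = sf.sample_camera_pose(sampled_spec, sf.PoseConfig(), seed=0)
        fr = sf.render_frame(sampled_spec, pose, sf.RenderConfig(image_size=32))
        scale = 0.002
        rec = sf.FrameRecord("s", "plain", 0, "s/p/rgb_000000.png",
                             "s/p/depth_000000.png", "s/p/mask_000000.png",
                             "s/p/meta_000000.json")
        sf.write_frame(fr, str(tmp_path), rec, scale)
        man = sf.DatasetManifest(root=str(tmp_path), depth_scale=scale,
                                 frames=[rec], split={"s": "train"})
        back = sf.load_frame(man, rec)
        assert np.max(np.abs(back.depth[fr.mask] - fr.depth[fr.mask])) \
            <= scale / 2 + 1e-9

    def test_same_config_seed_byte_identical_manifests(self, tmp_path):
        cfg1 = sf.DatasetConfig(n_models=1, images_per_model_per_material=2,
                                out_dir=str(tmp_path / "a"), image_size=32)
        cfg2 = dataclasses.replace(cfg1, out_dir=str(tmp_path / "b"))
        sf.generate_dataset(cfg1, seed=3)
        sf.generate_dataset(cfg2, seed=3)
        a = (tmp_path / "a" / "manifest.json").read_bytes()
        b = (tmp_path / "b" / "manifest.json").read_bytes()
        assert a == b


class TestPartitionDataset:
    @pytest.mark.parametrize("args,expected", [
        ((38, 10000, 2, 2), (340000, 20000, 20000)),
        ((3, 10, 1, 1), (10, 10, 10)),
        ((5, 100, 2, 1), (200, 200, 100)),
    ])
    def test_counts(self, args, expected):
        counts, assignment = sf.partition_dataset(*args)
        assert counts == expected
        assert len(assignment) == args[0]

    def test_split_is_by_model(self):
        _, assignment = sf.partition_dataset(10, 7, 2, 3)
        assert sorted(assignment) == list(range(10))
        from collections import Counter
        c = Counter(assignment.values())
        assert c == {"train": 5, "val": 2, "test": 3}

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            sf.partition_dataset(4, 10, 2, 2)
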