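import numpy as np
import pytest

from cystodepth import depth_net, scene_forge


@pytest.fixture(scope="session")
def sphere_spec():
    """Undeformed sphere of radius 30 mm, plain material."""
    return scene_forge.SceneSpec(
        scene_id="sphere", base_radius=30.0, deform_amplitudes=(),
        perlin_params=(1, 1.0, 0.0), polyps=(), material="plain",
        texture_params=((0.8, 0.3, 0.3), 2.0, 0.5, 1.0),
        light_params=(60.0, 90.0, 2.0))


@pytest.fixture(scope="session")
def center_pose():
    return scene_forge.CameraPose(position=(0.0, 0.0, 0.0),
                                  view_dir=(0.0, 0.0, 1.0),
                                  up=(0.0, 1.0, 0.0), fov=70.0)


@pytest.fixture(scope="session")
def sampled_spec():
    return scene_forge.sample_scene_spec(scene_forge.SceneGenConfig(), seed=5)


@pytest.fixture(scope="session")
def rendered_frame(sampled_spec):
    pose = scene_forge.sample_camera_pose(
        sampled_spec, scene_forge.PoseConfig(), seed=3)
    return scene_forge.render_frame(
        sampled_spec, pose, scene_forge.RenderConfig(image_size=64))


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return depth_net.NetworkConfig(n_encoder_levels=5, base_channels=4,
                                   channel_cap=32, input_size=64)


@pytest.fixture()
def tiny_net(tiny_net_cfg):
    return depth_net.build_depth_network(tiny_net_cfg, seed=0)


@pytest.fixture(scope="session")
def image_batch():
    rng = np.random.default_rng(7)
    return rng.uniform(0.0, 1.0, size=(4, 64, 64, 3))
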