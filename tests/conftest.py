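import numpy as np
import pytest
from hypothesis import settings

from fallfusion.model_4s3dcnn import ModelConfig
from fallfusion.synthetic_falls import SceneConfig, make_dataset
from fallfusion.windowing import WindowSpec, build_sample_set

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_model_cfg():
    """Full four-branch topology with 8x fewer filters: same shapes rules,
    a fraction of the arithmetic."""
    return ModelConfig(
        branch_conv_filters=(8, 16, 32),
        conv_kernels=((4, 4, 3), (3, 3, 8), (3, 3, 16)),
        conv_strides=((2, 2, 3), (2, 2, 8), (1, 1, 16)),
        fc_widths=(16, 8, 4),
    )


@pytest.fixture(scope="session")
def small_scene_cfg():
    """Low-resolution short clips for fast end-to-end tests."""
    return SceneConfig(
        image_size=(120, 160),
        n_clips_per_class=6,
        frame_count_range=(21, 26),
        actor_half_axes=(28.0, 8.0),
        fall_duration=12,
        sit_duration=10,
        floor_margin=6,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scene_cfg):
    """Fused sample set (~50 windows) from the small synthetic scene."""
    clips, _ = make_dataset(small_scene_cfg)
    return build_sample_set(clips, WindowSpec())
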