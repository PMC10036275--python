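import numpy as np
import pytest

from crownscorch.synthetic import SceneConfig, TreeTruth, generate_scene


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SceneConfig(color_noise_sd=0.0, shadow_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_scene(noiseless_cfg):
    """Well-separated mixed-severity stand, noiseless, fully seeded."""
    from crownscorch.synthetic import random_truths

    truths = random_truths(8, noiseless_cfg, min_spacing=5.0)
    return generate_scene(truths, noiseless_cfg)


@pytest.fixture(scope="session")
def single_cone_scene(noiseless_cfg):
    """One unburned 12-m cone of crown radius 2 m centered in the plot."""
    truth = TreeTruth(
        tree_id=1, stem_x=0.0, stem_y=0.0, total_height=12.0,
        crown_base_height=3.0, scorch_height=0.0, crown_radius=2.0,
    )
    return generate_scene([truth], noiseless_cfg), truth
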