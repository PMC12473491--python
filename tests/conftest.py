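import numpy as np
import pytest

from sesame3d import (
    default_plant_spec,
    generate_plant,
    generate_scene,
    make_adhesion_case,
)


@pytest.fixture(scope="session")
def default_plant():
    """Standard 6-leaf synthetic plant, noiseless, flat leaves."""
    from dataclasses import replace

    spec = default_plant_spec(seed=1)
    spec = replace(spec, leaves=[replace(l, droop_deg=0.0) for l in spec.leaves])
    labeled, truth = generate_plant(spec)
    return spec, labeled, truth


@pytest.fixture(scope="session")
def default_scene(default_plant):
    spec, labeled, truth = default_plant
    scene, info = generate_scene(labeled, spec)
    return spec, scene, info, truth


@pytest.fixture(scope="session")
def adhesion_scene():
    """6 leaves in 3 touching pairs with crease contact regions."""
    spec = default_plant_spec(seed=3, n_leaves=6)
    labeled, truth = make_adhesion_case(spec, [(0, 1), (2, 3), (4, 5)])
    return spec, labeled, truth


@pytest.fixture(scope="session")
def tiny_training_set():
    """Five reduced-density plants for CPU training experiments."""
    from sesame3d import random_plant_spec

    clouds, labels = [], []
    for seed in range(5):
        spec = random_plant_spec(seed, density_scale=0.1)
        labeled, _ = generate_plant(spec)
        clouds.append(
            np.concatenate([labeled.cloud.coords, labeled.cloud.colors], axis=1)
        )
        labels.append(labeled.semantic)
    return clouds, labels
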