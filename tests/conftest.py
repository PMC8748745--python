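import numpy as np
import pytest
from hypothesis import settings

import memseg3d as m

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless, hole-free 48^3 phantom with 12 cells and its ground truth."""
    spec = m.PhantomSpec(extent=(48, 48, 48), n_cells=12, noise_sd=0.0,
                         hole_rate=0.0, seed=5)
    image, labels = m.generate_phantom(spec)
    masks = m.semantic_masks_from_labels(labels, spec.membrane_thickness)
    return spec, image, labels, masks


@pytest.fixture(scope="session")
def tiny_trained_net(small_phantom):
    """A small network trained briefly on the small phantom (seeded)."""
    spec, image, labels, _ = small_phantom
    cfg = m.TrainConfig(cuboid_min=(16, 16, 16), cuboid_max=(20, 20, 20),
                        batch_size=2, steps=60, learning_rate=2e-3, seed=1)
    net_cfg = m.NetworkConfig(n_levels=2, base_channels=8)
    net, log = m.train_semantic_model([(image, labels)], cfg, net_cfg)
    return net, log


def random_probability_stack(rng, shape):
    p = rng.random((3,) + shape)
    return p / p.sum(axis=0)


def random_onehot_masks(rng, shape):
    idx = rng.integers(0, 3, shape)
    return np.eye(3)[idx].transpose(3, 0, 1, 2)
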