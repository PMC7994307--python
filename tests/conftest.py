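"""Shared fixtures: small seeded stimulus sets and extractors.

Canvas sizes are kept small (48–96 px) so the suite runs quickly; every
generator is exercised at full study-scale counts in the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from visprobe import features, stimuli

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

SIZE = 64


@pytest.fixture(scope="session")
def thatcher_set():
    return stimuli.make_thatcher_set(4, seed=11, size=96)


@pytest.fixture(scope="session")
def mirror_set():
    return stimuli.make_mirror_set(6, seed=3, size=SIZE)


@pytest.fixture(scope="session")
def scene_set():
    return stimuli.make_scenes(5, seed=4, size=SIZE)


@pytest.fixture(scope="session")
def multiobject_set():
    return stimuli.make_multiobject_displays(8, 25, 25, seed=5, size=SIZE)


@pytest.fixture(scope="session")
def shape_set():
    # reduced texture/silhouette counts for speed; full counts in acceptance
    return stimuli.make_shape_sets(seed=6, size=SIZE, n_textures=16,
                                   n_silhouettes=16)


@pytest.fixture(scope="session")
def bar_set():
    return stimuli.make_length_bars(None, seed=7, size=224)


@pytest.fixture(scope="session")
def size_tetrads():
    return stimuli.make_size_tetrads(6, seed=8, size=SIZE)


@pytest.fixture(scope="session")
def surface_tetrads():
    return stimuli.make_surface_tetrads(3, 2, seed=9, size=SIZE)


@pytest.fixture(scope="session")
def threed_set():
    return stimuli.make_3d_pairs(seed=10, size=96)


@pytest.fixture(scope="session")
def occlusion_set():
    return stimuli.make_occlusion_displays(seed=12, size=96)


@pytest.fixture(scope="session")
def part_set():
    return stimuli.make_part_objects(seed=13, size=SIZE)


@pytest.fixture(scope="session")
def hierarchical_set():
    return stimuli.make_hierarchical_stimuli(seed=14, size=SIZE)


@pytest.fixture(scope="session")
def pixel():
    return features.pixel_extractor()


@pytest.fixture(scope="session")
def refnet():
    return features.reference_convnet(seed=0, width_scale=0.5, input_size=32)


def constant_table(vectors_by_layer, layer_kinds=None):
    """Build an ActivationTable directly from per-layer (n, dim) arrays."""
    mats = [np.asarray(m, dtype=float) for m in vectors_by_layer]
    kinds = layer_kinds or ["fc"] * len(mats)
    layers = [features.LayerSpec(k, f"L{k}", kinds[k]) for k in range(len(mats))]
    return features.ActivationTable(layers, mats, mats[0].shape[0])
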