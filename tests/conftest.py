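import numpy as np
import pytest

from cropsense.synthetic_data import (SceneConfig, generate_scene,
                                      render_marker_image, sample_point_clouds,
                                      sparse_labels)
from cropsense.image_height import train_pixel_classifier


@pytest.fixture(scope="session")
def small_scene():
    """A reduced field (40 m x 12 m) that keeps point-cloud tests fast."""
    return generate_scene(SceneConfig(field_length=40.0, field_width=12.0,
                                      road_center_x=10.0, seed=7))


@pytest.fixture(scope="session")
def small_clouds(small_scene):
    return sample_point_clouds(small_scene, seed=8)


@pytest.fixture(scope="session")
def trained_classifier():
    """Random forest trained on 8 sparsely labeled rendered marker images."""
    rng = np.random.default_rng(42)
    labeled = []
    for k in range(8):
        h = float(rng.uniform(20, 180))
        img, truth = render_marker_image(h, seed=100 + k)
        labeled.append((img, sparse_labels(truth, fraction=0.02, seed=200 + k)))
    return train_pixel_classifier(labeled, n_trees=50, seed=0)
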