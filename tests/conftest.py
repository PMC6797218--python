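import numpy as np
import pytest

from ploidyscope import generate_scene, preset_config


@pytest.fixture(scope="session")
def small_scene():
    """One modest naked-mole-rat-style scene shared by read-only tests."""
    cfg = preset_config("hglaber", n_cardiomyocytes=60, n_endothelial=35,
                        seed=11, image_shape=(600, 600))
    stack, truth = generate_scene(cfg)
    return cfg, stack, truth


def match_to_truth(nuclei, truth):
    """Map detected nuclei to ground-truth nucleus labels by centroid containment."""
    mask = truth.nucleus_mask
    iy = np.clip(np.rint(nuclei["cy"]).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip(np.rint(nuclei["cx"]).astype(int), 0, mask.shape[1] - 1)
    return mask[iy, ix]
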