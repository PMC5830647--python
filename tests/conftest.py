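import numpy as np
import pytest

from fiberseg import (PatchSet, ScalarImage, extract_patches, rasterize,
                      render, sample_population, split_train_val)
from fiberseg.synthetic import RenderSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_scene():
    """One 1024x1024 synthetic TEM-like scene with its ground truth."""
    pop = sample_population(60, canvas_size=102.4, pixel_size=0.1, seed=7)
    mask = rasterize(pop)
    img = render(mask, RenderSpec(polarity="tem"), seed=8)
    return pop, mask, img


def make_patchset(n_images: int, seed: int = 0, polarity: str = "tem") -> PatchSet:
    """n_images synthetic 1024^2 scenes tiled into 512^2 patches, 70/30 split."""
    patches, origins = [], []
    for i in range(n_images):
        pop = sample_population(60, canvas_size=102.4, pixel_size=0.1, seed=seed + i)
        mask = rasterize(pop)
        img = render(mask, RenderSpec(polarity=polarity), seed=seed + 100 + i)
        ps = extract_patches(ScalarImage(img.pixels, 0.1), mask)
        patches += ps.patches
        origins += ps.origins
    pset = PatchSet(patches, origins, pixel_size=0.1)
    return split_train_val(pset, 0.7, seed=seed)
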