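import numpy as np
import pytest

from deeplof.imaging import PseudoColorImage
from deeplof.synthetic import CohortSpec, generate_cohort, generate_texture_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40/14 cohort at 48 px — large enough to exercise the full stack,
    small enough to keep the suite fast."""
    spec = CohortSpec(n_normal=40, n_abnormal=14, n_textures=10,
                      image_size=48, seed=7)
    return generate_cohort(spec), generate_texture_library(10, size=64, seed=8)


def toy_three_class_set(n_per_class: int = 8, size: int = 12, seed: int = 0):
    """Linearly separable toy images: class 0 dark, class 1 bright,
    class 2 half-and-half — trivially separable by mean intensity."""
    rng = np.random.default_rng(seed)
    items = []
    for label, base in ((0, 0.12), (1, 0.88), (2, 0.5)):
        for i in range(n_per_class):
            img = np.clip(base + rng.normal(0, 0.04, (size, size, 3)), 0, 1)
            if label == 2:
                img[: size // 2] = np.clip(img[: size // 2] + 0.35, 0, 1)
                img[size // 2:] = np.clip(img[size // 2:] - 0.35, 0, 1)
            items.append(PseudoColorImage(img, f"toy{label}_{i}", label))
    return items
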