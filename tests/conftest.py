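import numpy as np
import pytest

from psnseg.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small, fast cohort used across I/O and training-plumbing tests."""
    return PhantomConfig(
        grid_shape=(32, 32, 32),
        spacing_mm=(3.0, 3.0, 3.0),
        n_patients=3,
        n_test_patients=1,
        n_fractions=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_cohort")
    return generate_cohort(tiny_config, out)


def random_blob(rng: np.random.Generator, shape=(10, 10, 10)) -> np.ndarray:
    """Random nonempty binary mask: a thresholded smooth noise field."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    mask = (field > np.quantile(field, 0.8)).astype(np.uint8)
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = 1
    return mask
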