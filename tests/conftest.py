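import numpy as np
import pytest

from slide2rx import (
    SlideImage,
    SyntheticCohortSpec,
    TrainingConfig,
    cohort_to_dataset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny matched cohort (10 patients, 4 tissue tiles each)."""
    spec = SyntheticCohortSpec(n_patients=10, n_genes=60, n_driven_genes=15, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return cohort_to_dataset(small_cohort, tranche_size=40)


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale training config (the full-scale defaults are far slower)."""
    return TrainingConfig(learning_rate=3e-3, max_epochs=25, patience=6, seed=7)


@pytest.fixture(scope="session")
def fast_ae_config():
    return TrainingConfig(learning_rate=1e-3, max_epochs=6, patience=3, seed=7)


@pytest.fixture()
def checkerboard_slide():
    """A 1024x1024 slide: fine high-contrast checkerboard, gradients everywhere."""
    n = 1024
    yy, xx = np.mgrid[0:n, 0:n]
    checker = (((yy // 2) + (xx // 2)) % 2 * 255).astype(np.uint8)
    return SlideImage("chk", "pchk", np.stack([checker] * 3, axis=-1))
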