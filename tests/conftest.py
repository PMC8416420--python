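import numpy as np
import pytest

from virtsamp.volume import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    """Small 1 mm isotropic grid with an identity-aligned affine."""
    return Grid((40, 48, 40), np.eye(4))


@pytest.fixture
def mm2_grid():
    """2 mm isotropic grid centered on the world origin."""
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = [-39.0, -47.0, -39.0]
    return Grid((40, 48, 40), aff)


def random_mask(grid: Grid, rng: np.random.Generator, p: float = 0.2) -> np.ndarray:
    return (rng.random(grid.shape) < p).astype(np.uint8)


@pytest.fixture(scope="session")
def default_cohort20():
    """The reference synthetic cohort: n=20 subjects, default variability
    (6 mm AP landmark jitter), master seed 1.  Session-scoped because several
    cohort-level properties are checked against the same run."""
    from virtsamp.phantom import make_cohort

    return make_cohort(n=20, master_seed=1, make_images=False)


@pytest.fixture(scope="session")
def accuracy20(default_cohort20):
    """Accuracy stage (all three methods) on the reference cohort."""
    from virtsamp.pipeline import RunConfig, run_accuracy

    return run_accuracy(default_cohort20, RunConfig(seed=1))
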