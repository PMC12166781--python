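import numpy as np
import pytest

from peerce.experiments import learned_recovery, oracle_recovery
from peerce.synth import SyntheticSlideSpec, generate_slide


def mini_spec(**overrides) -> SyntheticSlideSpec:
    """A small, fast slide spec for unit tests (not the cohort conditions)."""
    base = dict(canvas_size=(1536, 1536), tissue_blobs=2,
                blob_semiaxis_range=(400.0, 600.0), n_cells=120,
                true_tps=25.0, oc_fraction=0.3, rng_seed=11)
    base.update(overrides)
    return SyntheticSlideSpec(**base)


@pytest.fixture(scope="session")
def mini_slide():
    spec = mini_spec()
    image, gt = generate_slide(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def oracle_result():
    """Oracle-backend TPS recovery on the 10-slide held-out span."""
    return oracle_recovery(seed=1)


@pytest.fixture(scope="session")
def learned_result():
    """Toy-trained pipeline TPS recovery on the 10-slide held-out span."""
    return learned_recovery(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
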