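import numpy as np
import pytest

from icasurv import synthetic


@pytest.fixture(scope="session")
def small_atlas():
    return synthetic.make_source_atlas(4, (12, 12, 12), blob_radius=2.0, seed=3)


@pytest.fixture(scope="session")
def reference_cohort(small_atlas):
    """Noiseless two-group cohort used across ICA/selection tests."""
    return synthetic.simulate_reference_cohort(
        small_atlas, n_per_group=25, group_shift=1.5, noise_sd=0.0, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
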