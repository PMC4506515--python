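import numpy as np
import pytest

from confex.synthetic_data import paper_scenario


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Published-truth scenario with every noise source switched off."""
    return paper_scenario(
        seed=0, zz_noise=0.0, ls_noise=0.0, pfg_noise=0.0, sf_noise=0.0,
        sf_rate_noise=0.0, assay_noise=0.0, itc_noise_ucal=0.0,
        melt_noise=0.0, mexico_noise=0.0,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """Published-truth scenario at instrument-typical noise."""
    return paper_scenario(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
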