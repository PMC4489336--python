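import numpy as np
import pytest

from wgsig.synthetic import CohortSpec, generate_founders, sample_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        n_individuals=200,
        n_sites=6000,
        n_founder_haplotypes=400,
        copy_switch_rate=0.005,
        maf_spectrum_exponent=1.1,
        freq_min=2e-3,
        freq_max=0.5,
        founder_ld_scale=100.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sample_cohort(generate_founders(small_spec), small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
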