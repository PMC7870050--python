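import logging

import numpy as np
import pytest

from fracturetwist.cohort import (default_generator_spec, generate_cohort,
                                  null_spec, planted_signal_spec)

# silence the expected clipping warnings from applying training ranges to test data
logging.getLogger("fracturetwist.preprocessing").setLevel(logging.ERROR)

make_planted_spec = planted_signal_spec
make_noise_spec = null_spec


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_generator_spec(), n_total=172, seed=1)


@pytest.fixture(scope="session")
def planted_cohort():
    return generate_cohort(make_planted_spec(), n_total=200, seed=3)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
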