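import numpy as np
import pytest

from fakesim import GenerativeParams, OrdinalMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)


@pytest.fixture
def small_matrix():
    values = np.array(
        [
            [1, 3, 5, 2],
            [2, 2, 4, 4],
            [5, 1, 3, 3],
        ]
    )
    return OrdinalMatrix(values, q=5)


@pytest.fixture
def study_params():
    """The generative configuration used throughout: 5-point items,
    binomial-shaped symmetric marginals, medium uniform correlation."""
    return GenerativeParams(n=126, m=12, q=5, p_binom=0.5, rho_target=0.25, seed=11)


@pytest.fixture
def generated_matrix(study_params):
    from fakesim import generate_true_data

    return generate_true_data(study_params)
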