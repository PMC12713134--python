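import numpy as np
import pytest

from syllnet import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_config():
    """Small cohort for fast end-to-end tests."""
    return CohortConfig(
        n_syllables=10,
        seq_length=150,
        n_animals_per_group=3,
        return_bias=0.35,
        baseline_return_bias=0.05,
        group_specific_ids=frozenset({8, 9}),
        racing_ids=frozenset({8}),
        racing_boost=4.0,
        length_factor=0.8,
        seed=11,
    )


@pytest.fixture
def plain_config():
    """Single shared vocabulary, no racing, for analytic checks."""
    def make(n=11, rho=0.0, T=5000, seed=0, **kw):
        return CohortConfig(
            n_syllables=n,
            seq_length=T,
            n_animals_per_group=5,
            return_bias=rho,
            baseline_return_bias=rho,
            group_specific_ids=frozenset(),
            racing_ids=frozenset(),
            racing_boost=1.0,
            length_factor=1.0,
            seed=seed,
            **kw,
        )
    return make
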