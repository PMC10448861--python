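import numpy as np
import pytest

from epig4nn.synthetic import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """A small deterministic study fixture shared across test modules."""
    spec = FixtureSpec(
        n_chroms=4,
        chrom_length=16000,
        n_canonical=14,
        n_bulged=13,
        n_irregular=13,
        positive_fraction=0.2,
        paired_identical=4,
        window_width=250,
        seed=123,
    )
    return make_fixture(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
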