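import numpy as np
import pytest

from denovotx.synthetic import SyntheticSpec, generate_unigenes


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_study():
    """A small generated study shared by read-mapping and pipeline tests."""
    spec = SyntheticSpec(
        n_unigenes=25,
        length_log_mean=6.0,
        length_log_sd=0.3,
        library_sizes=(20000, 20000),
        seed=11,
    )
    unigenes, truth = generate_unigenes(spec)
    return spec, unigenes, truth


def random_dna(rng, length, p=None):
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
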