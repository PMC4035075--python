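import numpy as np
import pytest

from mirduplex.synth_data import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by read-only tests."""
    return generate_study(StudyConfig(n_tp=15, n_fn=15, n_decoys=3, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
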