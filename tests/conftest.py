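import numpy as np
import pytest

from rloopmap import simgen


@pytest.fixture(scope="session")
def small_allele():
    """A compact allele (short flanks) to keep alignment-heavy tests fast."""
    spec = simgen.AlleleSpec(n_units=20, flank_5_len=250, flank_3_len=120, seed=11)
    return simgen.make_allele(spec)


@pytest.fixture(scope="session")
def default_allele():
    return simgen.make_allele(simgen.AlleleSpec(n_units=30, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
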