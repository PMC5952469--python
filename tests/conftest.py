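import numpy as np
import pytest

from hybscan import synth

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), n))


@pytest.fixture(scope="session")
def trio_cohort():
    """One trio scenario (two haploids + their hybrid), fixed seed."""
    return synth.generate(synth.preset_scenario("trio", seed=11))


@pytest.fixture(scope="session")
def cohort12():
    """One 12-strain scenario (7 hybridization events), fixed seed."""
    return synth.generate(synth.preset_scenario("cohort12", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
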