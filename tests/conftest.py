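import numpy as np
import pytest

from nappan.core_model import (GeneFeature, GenomeRecord, Replicon, Thresholds,
                               load_fixture)
from nappan.nap_identify import census_from_fixture


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def table1_census():
    return census_from_fixture(load_fixture("table1_census"))


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_plasmids")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4_imges")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_replicon():
    return Replicon(replicon_id="chr", length_bp=100_000, topology="circular",
                    kind="chromosome", ori_pos=1, ter_pos=50_000)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def random_dna(rng, length, with_n=False):
    alphabet, p = list("ACGT"), None
    if with_n:
        alphabet, p = list("ACGTN"), [0.24, 0.24, 0.24, 0.24, 0.04]
    return "".join(rng.choice(alphabet, p=p, size=length))
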