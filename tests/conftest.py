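import numpy as np
import pytest

from gxepi import make_fixture
from gxepi.core_data import AnalysisConfig


@pytest.fixture(scope="session")
def tiny_synergy():
    return make_fixture("tiny-synergy")


@pytest.fixture(scope="session")
def tiny_null():
    return make_fixture("tiny-null")


@pytest.fixture(scope="session")
def tiny_monovariant():
    return make_fixture("tiny-monovariant")


@pytest.fixture()
def config():
    return AnalysisConfig()


# Adjusted odds-ratio triples (drug+/wild, drug-/carrier, drug+/carrier) from
# the published interaction table, with the printed RERI and S values they
# imply.  Used both as worked examples and as regression anchors.
PUBLISHED_OR_TRIPLES = [
    # (label, or10, or01, or11, reri_printed, s_printed)
    ("rs2180314_any_nsaid", 3.17, 0.74, 7.30, 4.39, 3.30),
    ("rs2180314_non_aspirin", 2.89, 0.75, 6.61, 3.97, 3.42),
    ("rs4809957_any_nsaid", 4.12, 0.99, 7.57, 3.46, 2.11),
    ("rs6664_any_nsaid", 7.47, 1.13, 6.15, -1.45, 0.78),
    ("rs4715332_any_nsaid", 4.76, 0.88, 6.98, 2.34, 1.64),
    ("rs1695_any_nsaid", 5.70, 0.82, 5.41, -0.11, 0.98),
]
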