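import pytest

from trbrep.germline import Cluster, GermlineGene, LocusModel
from trbrep.simulate import fixture_anchor, make_fixture_locus
from trbrep.stats import load_table1


@pytest.fixture(scope="session")
def fixture_locus():
    return make_fixture_locus(0)


@pytest.fixture(scope="session")
def locus(fixture_locus):
    return fixture_locus.locus


@pytest.fixture(scope="session")
def markers(fixture_locus):
    return fixture_locus.markers


@pytest.fixture(scope="session")
def alleles(fixture_locus):
    return fixture_locus.alleles


@pytest.fixture(scope="session")
def anchor():
    return fixture_anchor()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


# -- a small fully hand-controlled two-cluster locus for junction unit tests --

HAND_DX = "GATTACAGGCAT"
HAND_DY = "CCGTTGAACTGA"
HAND_JX = "ACGTACGTACGT" + "TTTGGAGCTGGC" + "ACCGTGACC"
HAND_JY = "GGCATTACCAGT" + "TTTGGACATGGC" + "GTTACCGTC"


def _hand_c(name, cid):
    return GermlineGene(name, "C", cid, "ATGGCCACC", exons=((0, 9),))


@pytest.fixture(scope="session")
def hand_locus():
    cx = Cluster(
        "X",
        GermlineGene("TRBDX", "D", "X", HAND_DX),
        (GermlineGene("TRBJX.1", "J", "X", HAND_JX),),
        _hand_c("TRBCX", "X"),
        1,
    )
    cy = Cluster(
        "Y",
        GermlineGene("TRBDY", "D", "Y", HAND_DY),
        (GermlineGene("TRBJY.1", "J", "Y", HAND_JY),),
        _hand_c("TRBCY", "Y"),
        2,
    )
    return LocusModel(clusters=(cx, cy))
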