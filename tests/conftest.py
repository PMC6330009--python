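import numpy as np
import pytest

from pathway_uq import parse_model
from pathway_uq.synthetic import camkii_network, demo_network

AB_TSV = """\
!!Species
Name\tRole\tDefaultTotal
A\telementary\t2
B\telementary\t2
C\tcomplex\t0
!!Reaction
Id\tFormula\tKind\tRateExpression
R1\tA + B <=> C\tmass_action_reversible\t
"""

TRIANGLE_TSV = """\
!!Species
Name\tRole\tDefaultTotal
A\telementary\t1
B\telementary\t1
C\telementary\t1
!!Reaction
Id\tFormula\tKind\tRateExpression
R1\tA <=> B\tmass_action_reversible\t
R2\tB <=> C\tmass_action_reversible\t
R3\tA <=> C\tmass_action_reversible\t
"""

CHAIN_TSV = """\
!!Species
Name\tRole\tDefaultTotal
A\telementary\t1
B\telementary\t1
C\telementary\t1
!!Reaction
Id\tFormula\tKind\tRateExpression
R1\tA <=> B\tmass_action_reversible\t
R2\tB <=> C\tmass_action_reversible\t
"""


@pytest.fixture(scope="session")
def ab_net():
    return parse_model(AB_TSV)


@pytest.fixture(scope="session")
def triangle_net():
    return parse_model(TRIANGLE_TSV)


@pytest.fixture(scope="session")
def chain_net():
    return parse_model(CHAIN_TSV)


@pytest.fixture(scope="session")
def demo_net():
    return demo_network()


@pytest.fixture(scope="session")
def camkii_net():
    return camkii_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
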