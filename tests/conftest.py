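import numpy as np
import pytest

from solvcontact import builtin_table, fixtures


@pytest.fixture(scope="session")
def table37():
    return builtin_table("extended37")


@pytest.fixture(scope="session")
def table23():
    return builtin_table("basic23")


@pytest.fixture(scope="session")
def toy_molecules():
    """All builtin toy templates, keyed by name."""
    return {name: fixtures.make_toy(name)
            for name in ("methane", "ethanol", "benzene", "acetamide", "dimethyl_ether")}


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


ETHANOL_MOL2 = """\
@<TRIPOS>MOLECULE
ethanol
9 8 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C1  0.0000  0.0000  0.0000 C.3 1 UNL 0.0
2 C2  1.5400  0.0000  0.0000 C.3 1 UNL 0.0
3 O1  2.0166  1.3482  0.0000 O.3 1 UNL 0.0
4 H1 -0.3633 -0.5138  0.8900 H   1 UNL 0.0
5 H2 -0.3633 -0.5138 -0.8900 H   1 UNL 0.0
6 H3 -0.3633  1.0277  0.0000 H   1 UNL 0.0
7 H4  1.9033 -0.5138  0.8900 H   1 UNL 0.0
8 H5  1.9033 -0.5138 -0.8900 H   1 UNL 0.0
9 H6  1.6970  1.8590  0.7500 H   1 UNL 0.0
@<TRIPOS>BOND
1 1 2 1
2 2 3 1
3 1 4 1
4 1 5 1
5 1 6 1
6 2 7 1
7 2 8 1
8 3 9 1
"""


@pytest.fixture(scope="session")
def ethanol_mol2_text():
    return ETHANOL_MOL2
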