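import pytest

import forestdyn as fd
from forestdyn.params import species_table


@pytest.fixture(scope="session")
def sp():
    return species_table()


@pytest.fixture(scope="session")
def default_outputs():
    """The default-condition study run: 10^4 cells, four scenarios,
    2010-2055, seeded.  Shared by the pattern and acceptance tests."""
    return fd.run_all(fd.RunConfig(seed=1, n_cells=10_000))


@pytest.fixture()
def small_landscape(sp):
    return fd.generate_landscape(50, seed=3, species=sp)
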