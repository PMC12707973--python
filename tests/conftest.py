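import numpy as np
import pytest

from tdhsi.spectra import ExtinctionTable, WavelengthGrid
from tdhsi.unmixing import build_design_matrix


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def table():
    return ExtinctionTable.vendored()


@pytest.fixture(scope="session")
def design_matrix(grid, table):
    return build_design_matrix(grid, table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
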