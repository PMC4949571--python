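import numpy as np
import pytest

from ptkie import io, pt_fitting


@pytest.fixture(scope="session")
def table1():
    """The packaged published rate table (4 series x 9 pressures)."""
    return io.load_table1_rates()


@pytest.fixture(scope="session")
def table2():
    """Published pressure-fit parameters as a DataFrame."""
    return io.load_table2_params()


@pytest.fixture(scope="session")
def table3():
    """Published cross-system KIE signature rows."""
    return io.load_table3_summaries()


@pytest.fixture(scope="session")
def table1_fits(table1):
    """Weighted refits of all four published rate series."""
    return {key: pt_fitting.fit_pressure_series(s) for key, s in table1.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240925)
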