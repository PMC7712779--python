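import numpy as np
import pytest

from amp_arsenal import synthetic_panel


@pytest.fixture(scope="session")
def table1():
    return synthetic_panel.load_table1()


@pytest.fixture(scope="session")
def panel_proteins():
    return synthetic_panel.panel_proteins()


@pytest.fixture(scope="session")
def panel_cds():
    return synthetic_panel.panel_cds()


@pytest.fixture(scope="session")
def profiles():
    return synthetic_panel.panel_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(20201203)
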