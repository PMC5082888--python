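import numpy as np
import pytest

from nirsbundle import (
    ExtinctionTable,
    OpticalModelParams,
    default_layout,
    generate_paradigm,
    line_bundle_layout,
)

FS = 1.81


@pytest.fixture(scope="session")
def ext():
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def params(ext):
    return OpticalModelParams(wavelengths=ext.wavelengths)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def line_layout():
    return line_bundle_layout()


@pytest.fixture(scope="session")
def paradigm():
    return generate_paradigm(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
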