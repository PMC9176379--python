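import numpy as np
import pytest

from dosicomp import (
    ChromophoreSet,
    ScatterParams,
    default_extinction_library,
)


@pytest.fixture(scope="session")
def lib():
    return default_extinction_library()


@pytest.fixture(scope="session")
def lean_chrom():
    """Thin-SATT (muscle-dominated) reference composition."""
    return ChromophoreSet.from_summary(thbmb=125.2, sto2=67.1, water=73.0, fat=1.1)


@pytest.fixture(scope="session")
def fat_chrom():
    """Thick-SATT (adipose-dominated) reference composition."""
    return ChromophoreSet.from_summary(thbmb=19.4, sto2=63.0, water=11.3, fat=67.3)


@pytest.fixture(scope="session")
def lean_scatter():
    return ScatterParams.from_reported(a500=0.87, b=-1.28)


@pytest.fixture(scope="session")
def fat_scatter():
    return ScatterParams.from_reported(a500=0.85, b=-0.42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
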