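import numpy as np
import pytest

from naphl import NapHL, load_dataset


@pytest.fixture(scope="session")
def metrology() -> np.ndarray:
    return load_dataset("metrology").values


@pytest.fixture(scope="session")
def engineering() -> np.ndarray:
    return load_dataset("engineering").values


@pytest.fixture(scope="session")
def dist_11_06() -> NapHL:
    """The reference parameter point used throughout the property tables."""
    return NapHL(1.1, 0.6)
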