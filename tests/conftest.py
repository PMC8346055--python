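import numpy as np
import pytest

from cxvar.domains import DomainSegmentation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_segmentation():
    """A 30-residue protein with every segment represented."""
    return DomainSegmentation((
        ("NT", 1, 3), ("M1", 4, 6), ("E1", 7, 9), ("M2", 10, 12),
        ("CL", 13, 16), ("M3", 17, 19), ("E2", 20, 22), ("M4", 23, 25),
        ("CT", 26, 30),
    ))


@pytest.fixture
def cx_segmentation():
    from cxvar.domains import default_segmentation

    return default_segmentation()
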