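import numpy as np
import pytest

from beziermask import ShapeSpec, generate


@pytest.fixture(scope="session")
def blob_mask():
    """A smooth medium-sized Fourier blob with its analytic contour."""
    return generate(ShapeSpec("fourier_blob", 14000, seed=7))


@pytest.fixture(scope="session")
def rect_mask():
    """10x6 filled rectangle inset in a 20x20 frame."""
    m = np.zeros((20, 20), dtype=bool)
    m[5:11, 4:14] = True
    return m


@pytest.fixture(scope="session")
def dumbbell_mask():
    return generate(ShapeSpec("dumbbell", 12000, seed=5))[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
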