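import numpy as np
import pytest

from qcomplex import SimplicialComplex, reference_complex, worked_example_complex


@pytest.fixture
def k2() -> SimplicialComplex:
    """The shared-edge pair of triangles {⟨v1,v2,v3⟩, ⟨v2,v3,v4⟩}."""
    return worked_example_complex()


@pytest.fixture
def ref() -> SimplicialComplex:
    """Four-simplex documentation complex over seven vertices."""
    return reference_complex()


@pytest.fixture
def triangle_adj() -> np.ndarray:
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def path4_adj() -> np.ndarray:
    a = np.zeros((4, 4), dtype=int)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        a[i, j] = a[j, i] = 1
    return a
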