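import numpy as np
import pytest

from epinet.spectral import PseudoBooleanFunction

# five-site worked example: f = 12*x1*x4 - 3*x3 + 6*x1*x2*x5
# (1-indexed sites; bit i of a mask <-> site i+1)
MASK_14 = 0b01001     # sites 1 and 4
MASK_3 = 0b00100      # site 3
MASK_125 = 0b10011    # sites 1, 2, 5
WORKED_TERMS = [(MASK_14, 12.0), (MASK_3, -3.0), (MASK_125, 6.0)]


@pytest.fixture
def worked_example() -> PseudoBooleanFunction:
    return PseudoBooleanFunction(d=5, terms=list(WORKED_TERMS))


def dense_hadamard(d: int) -> np.ndarray:
    """Independent oracle: H built by Kronecker recursion from the 2x2 core."""
    h2 = np.array([[1.0, 1.0], [1.0, -1.0]])
    H = np.array([[1.0]])
    for _ in range(d):
        H = np.kron(h2, H)
    return H


def spectra_close(a: dict, b: dict, tol: float = 1e-8) -> bool:
    if set(a) != set(b):
        return False
    return all(abs(a[m] - b[m]) <= tol for m in a)
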