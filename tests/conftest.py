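import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def fd_gradient(comp, positions, h=1e-6):
    """Central finite-difference gradient of a CV component."""
    g = np.zeros_like(positions)
    for a in range(len(positions)):
        for k in range(3):
            pp = positions.copy()
            pm = positions.copy()
            pp[a, k] += h
            pm[a, k] -= h
            g[a, k] = (comp.evaluate(pp)[0] - comp.evaluate(pm)[0]) / (2 * h)
    return g
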