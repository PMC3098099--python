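import numpy as np
import pytest

from duonorm.arraydata import ProbeLayout, TwoColourArray, compute_ma


def make_array(cy5, cy3, weight=None, duplicates=False, compute=True):
    """Build a TwoColourArray from raw channel vectors (test helper)."""
    cy5 = np.asarray(cy5, float)
    n = cy5.size
    if duplicates:
        ids = [f"ab{i // 2:04d}" for i in range(n)]
    else:
        ids = [f"ab{i:04d}" for i in range(n)]
    layout = ProbeLayout(antibody_id=np.array(ids, dtype=object),
                         duplicate_group=np.array(ids, dtype=object))
    arr = TwoColourArray(layout=layout, cy5=cy5, cy3=np.asarray(cy3, float),
                         weight=weight)
    return compute_ma(arr) if compute else arr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def biased_selfself(rng):
    """A self-self array with a smooth nonlinear dye bias and mild noise."""
    n = 600
    a = rng.normal(10.0, 1.8, n)
    bias = 0.4 * np.sin(a / 2.0)
    m = bias + rng.normal(0.0, 0.08, n)
    cy5 = 2.0 ** (a + m / 2.0)
    cy3 = 2.0 ** (a - m / 2.0)
    return make_array(cy5, cy3), a, bias
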