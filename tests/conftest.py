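import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_samples():
    """Fixed 6-point 2-D training set with both classes, not separable by a line."""
    X = np.array([[3.1, 0.10], [2.7, 0.15], [3.4, 0.12],
                  [4.2, 0.04], [4.5, 0.05], [3.6, 0.03]])
    y = np.array([1, 1, 1, -1, -1, -1])
    return X, y
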