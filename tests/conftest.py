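import numpy as np
import pytest

from pbmkit.motif_scan import MotifMatrix


@pytest.fixture
def simple_pwm():
    """Width-4 matrix with integer scores so float sums are exact."""
    scores = np.array(
        [
            [5.0, 0.0, 1.0, 0.0],
            [0.0, 6.0, 0.0, 1.0],
            [1.0, 0.0, 7.0, 0.0],
            [0.0, 1.0, 0.0, 5.0],
        ]
    )
    return MotifMatrix(name="toy", scores=scores, low_threshold=15.0)


@pytest.fixture
def ap2_like_pwm():
    """GC-rich matrix with a low/high threshold at 30 matrix units."""
    rng = np.random.default_rng(42)
    scores = rng.uniform(0.0, 6.0, size=(9, 4)).round(2)
    scores[:, 1] += 2.0  # favour C
    scores[:, 2] += 2.0  # favour G
    return MotifMatrix(name="ap2_like", scores=scores, low_threshold=30.0)


@pytest.fixture
def p53_like_pwm():
    rng = np.random.default_rng(7)
    scores = rng.uniform(0.0, 8.0, size=(10, 4)).round(2)
    return MotifMatrix(name="p53_like", scores=scores, low_threshold=50.0)
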