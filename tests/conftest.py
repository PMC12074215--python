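import math

import numpy as np
import pytest

from oeyolo.geometry import OrientedBox, canonicalize_box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, center_span=200.0, side_lo=4.0, side_hi=80.0) -> OrientedBox:
    """A random canonical oriented box (slender aspect ratios included)."""
    return canonicalize_box(
        OrientedBox(
            float(rng.uniform(-center_span, center_span)),
            float(rng.uniform(-center_span, center_span)),
            float(rng.uniform(side_lo, side_hi)),
            float(rng.uniform(side_lo, side_hi)),
            float(rng.uniform(-math.pi, math.pi)),
        )
    )
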