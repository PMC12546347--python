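import numpy as np
import pytest

from leafcount.geometry import BBox, Detection


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_boxes(rng, n, extent=200, max_size=60, labels=("adult", "nymph")):
    """Random valid detections inside an extent x extent image."""
    dets = []
    for _ in range(n):
        x0 = float(rng.integers(0, extent - 2))
        y0 = float(rng.integers(0, extent - 2))
        w = float(rng.integers(2, max_size))
        h = float(rng.integers(2, max_size))
        box = BBox(x0, y0, min(x0 + w, extent), min(y0 + h, extent))
        dets.append(
            Detection(
                box=box,
                label=str(rng.choice(labels)),
                confidence=float(np.round(rng.uniform(0.01, 1.0), 6)),
            )
        )
    return dets
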