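from __future__ import annotations

import numpy as np
import pytest

from berrypheno.annotation_io import DetectionInstance
from berrypheno.geometry import BinaryMask


def square_mask(frame, r0, c0, height, width):
    """A filled axis-aligned rectangle mask on the given frame."""
    m = np.zeros(frame, dtype=bool)
    m[r0 : r0 + height, c0 : c0 + width] = True
    return BinaryMask(m)


def disk_mask(frame, cy, cx, radius):
    """A rasterized disk (pixel centers within radius of an integer center)."""
    yy, xx = np.mgrid[0 : frame[0], 0 : frame[1]]
    return BinaryMask((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2)


def instance(mask, label="mature", score=None, image_id="img"):
    return DetectionInstance(image_id=image_id, label=label, score=score, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
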