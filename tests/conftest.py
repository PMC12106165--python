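import numpy as np
import pytest

from lidmorph import segmentation, synthgen
from lidmorph.palette import CORNEA, FISSURE, MARKER, SKIN
from lidmorph.segmentation import SegMask


@pytest.fixture(scope="session")
def normal_params():
    return synthgen.params_for_condition("normal", 12345, laterality="right")


@pytest.fixture(scope="session")
def normal_scene(normal_params):
    return synthgen.generate_scene(normal_params)


@pytest.fixture(scope="session")
def normal_eye(normal_scene):
    """(mask, box) for the segmented normal scene."""
    mask = segmentation.segment(normal_scene.image)
    boxes = segmentation.detect_eyes(mask)
    assert len(boxes) == 1
    return mask, boxes[0]


def make_disc_mask(radius: float, size: int | None = None, offset: float = 0.0,
                   label: int = MARKER) -> SegMask:
    """A skin canvas with one rasterized disc of the given label."""
    size = size or int(2 * radius + 20)
    yy, xx = np.mgrid[0:size, 0:size]
    cx = size / 2 + offset
    mask = np.full((size, size), SKIN, dtype=np.uint8)
    mask[(xx - cx) ** 2 + (yy - size / 2) ** 2 <= radius * radius] = label
    return SegMask(mask)


def make_rect_fissure(h: int = 60, w: int = 120, top: int = 20, bottom: int = 40,
                      x0: int = 10, x1: int = 110, cornea: tuple | None = None) -> SegMask:
    """A flat-margined (rectangular) fissure; optionally with a cornea disc."""
    mask = np.full((h, w), SKIN, dtype=np.uint8)
    mask[top : bottom + 1, x0 : x1 + 1] = FISSURE
    if cornea is not None:
        cx, cy, r = cornea
        yy, xx = np.mgrid[0:h, 0:w]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        mask[disc & (mask == FISSURE)] = CORNEA
    return SegMask(mask)
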