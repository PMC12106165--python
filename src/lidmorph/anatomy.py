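"""Anatomical region identification: lid-margin contours, canthi, region patches.

Coordinate convention (global): 0-based pixel indices, origin top-left,
x rightward, y downward; "vertical" runs along image columns.

The inner/outer canthus is the margin-contour endpoint nearest/furthest from
the nose.  In a monocular patch the nasal midline itself is unavailable, so
laterality substitutes for it: for the subject's right eye (left image half)
the nasal side is toward larger x, and mirrored for the left eye.  Horizontal
(x) distance is used, a documented interpretation of "nearest the midline".

The four region patches follow the published construction: canthus-centred
squares of side round(ICD/3) (round-half-to-even), and the minimum axis-
aligned bounding rectangle of each lid-margin polyline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import EyeBox, SegMask

__all__ = [
    "Landmarks",
    "RegionPatch",
    "RegionPatches",
    "AnatomyError",
    "extract_contours",
    "locate_canthi",
    "extract_regions",
]

REGIONS = ("inner_canthus", "outer_canthus", "upper_eyelid", "lower_eyelid")


class AnatomyError(ValueError):
    pass


@dataclass
class Landmarks:
    """Canthus points and lid-margin polylines, ordered inner → outer canthus."""

    inner_canthus: tuple[int, int]  # (x, y)
    outer_canthus: tuple[int, int]
    upper_margin: np.ndarray  # (N, 2) int array of (x, y), medial → lateral
    lower_margin: np.ndarray
    laterality: str

    def __post_init__(self) -> None:
        self.upper_margin = np.asarray(self.upper_margin, dtype=int)
        self.lower_margin = np.asarray(self.lower_margin, dtype=int)
        for chain in (self.upper_margin, self.lower_margin):
            if chain.ndim != 2 or chain.shape[1] != 2 or len(chain) == 0:
                raise AnatomyError("margin polylines must be non-empty (N, 2) arrays")
            if tuple(chain[0, 0:1]) != (self.inner_canthus[0],) or tuple(
                chain[-1, 0:1]
            ) != (self.outer_canthus[0],):
                raise AnatomyError("polylines must start/end at the canthus columns")
        if self.icd_px <= 0:
            raise AnatomyError("inter-canthal distance must be positive")

    @property
    def icd_px(self) -> float:
        dx = self.inner_canthus[0] - self.outer_canthus[0]
        dy = self.inner_canthus[1] - self.outer_canthus[1]
        return float(np.hypot(dx, dy))

    def margin_y_at(self, column: int, which: str) -> int:
        chain = self.upper_margin if which == "upper" else self.lower_margin
        hit = chain[chain[:, 0] == column]
        if len(hit) == 0:
            raise AnatomyError(f"column {column} outside the fissure span")
        return int(hit[0, 1])


@dataclass
class RegionPatch:
    """A sub-raster with its half-open pixel box (x0, y0, x1, y1)."""

    region: str
    box: tuple[int, int, int, int]
    image: np.ndarray
    mask: np.ndarray
    clipped: bool = False  # True when clamping removed > 50% of the nominal area

    @property
    def side(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.box
        return (y1 - y0, x1 - x0)


@dataclass
class RegionPatches:
    inner_canthus_patch: RegionPatch
    outer_canthus_patch: RegionPatch
    upper_eyelid_patch: RegionPatch
    lower_eyelid_patch: RegionPatch

    def __iter__(self):
        yield self.inner_canthus_patch
        yield self.outer_canthus_patch
        yield self.upper_eyelid_patch
        yield self.lower_eyelid_patch


def extract_contours(mask: SegMask, box: EyeBox) -> tuple[np.ndarray, np.ndarray]:
    """Split the fissure boundary into upper and lower margin chains.

    Per column inside the box, the topmost and bottommost eye-region pixel
    (fissure ∪ cornea) give the upper and lower margin.  The chains meet at
    the leftmost and rightmost fissure columns; a 1-px-tall fissure yields
    identical chains.  Chains are ordered medial → lateral per laterality.
    """
    eye = box.crop(mask.eye_pixels())
    cols = np.flatnonzero(eye.any(axis=0))
    if len(cols) == 0:
        raise AnatomyError("no fissure pixels inside the eye box")

    upper = []
    lower = []
    for c in cols:
        rows = np.flatnonzero(eye[:, c])
        x = int(c + box.x0)
        upper.append((x, int(rows[0] + box.y0)))
        lower.append((x, int(rows[-1] + box.y0)))
    upper_arr = np.asarray(upper, dtype=int)
    lower_arr = np.asarray(lower, dtype=int)
    if box.laterality == "right":
        # Nasal side is larger x: order medial → lateral = descending x.
        upper_arr = upper_arr[::-1]
        lower_arr = lower_arr[::-1]
    return upper_arr, lower_arr


def locate_canthi(
    contours: tuple[np.ndarray, np.ndarray], laterality: str
) -> Landmarks:
    """Canthi from the contour endpoints: nasal endpoint = inner canthus.

    At an extreme column the upper and lower chains may disagree on y when the
    fissure end is more than 1 px tall; the tie is broken toward smaller y.
    """
    upper, lower = contours
    if len(upper) == 0 or len(lower) == 0:
        raise AnatomyError("empty contour chains")

    def endpoint(i: int) -> tuple[int, int]:
        x = int(upper[i, 0])
        y = min(int(upper[i, 1]), int(lower[i, 1]))
        return (x, y)

    inner = endpoint(0)
    outer = endpoint(-1)
    return Landmarks(
        inner_canthus=inner,
        outer_canthus=outer,
        upper_margin=upper,
        lower_margin=lower,
        laterality=laterality,
    )


def _clamped_patch(
    region: str,
    x0: int,
    y0: int,
    x1: int,
    y1: int,
    image: np.ndarray,
    mask: SegMask,
) -> RegionPatch:
    h, w = mask.shape
    cx0, cy0 = max(0, x0), max(0, y0)
    cx1, cy1 = min(w, x1), min(h, y1)
    if cx0 >= cx1 or cy0 >= cy1:
        raise AnatomyError(f"{region} patch fully outside the image")
    nominal = (x1 - x0) * (y1 - y0)
    clipped = (cx1 - cx0) * (cy1 - cy0) < 0.5 * nominal
    return RegionPatch(
        region=region,
        box=(cx0, cy0, cx1, cy1),
        image=image[cy0:cy1, cx0:cx1],
        mask=mask.labels[cy0:cy1, cx0:cx1],
        clipped=clipped,
    )


def extract_regions(image: np.ndarray, mask: SegMask, lm: Landmarks) -> RegionPatches:
    """Decompose the eye into the four anatomical region patches."""
    side = int(round(lm.icd_px / 3))  # round-half-to-even
    side = max(side, 1)

    def canthus_patch(region: str, center: tuple[int, int]) -> RegionPatch:
        cx, cy = center
        x0 = cx - side // 2
        y0 = cy - side // 2
        return _clamped_patch(region, x0, y0, x0 + side, y0 + side, image, mask)

    def margin_patch(region: str, chain: np.ndarray) -> RegionPatch:
        x0, y0 = chain.min(axis=0)
        x1, y1 = chain.max(axis=0) + 1  # half-open
        return _clamped_patch(region, int(x0), int(y0), int(x1), int(y1), image, mask)

    return RegionPatches(
        inner_canthus_patch=canthus_patch("inner_canthus", lm.inner_canthus),
        outer_canthus_patch=canthus_patch("outer_canthus", lm.outer_canthus),
        upper_eyelid_patch=margin_patch("upper_eyelid", lm.upper_margin),
        lower_eyelid_patch=margin_patch("lower_eyelid", lm.lower_margin),
    )
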