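"""Baseline segmentation and eye detection on label masks.

The segmenter is a declared contract — any callable ``image -> SegMask`` can
stand in for the palette baseline (e.g. a learned network for clinical
photographs).  The baseline assigns every pixel to the nearest palette colour
and then tidies the result with :func:`clean_mask`.  Eye detection is
mask-driven: each connected interpalpebral-fissure blob yields one bounding
box, with laterality assigned by the frontal-photo convention (a blob in the
left image half is the subject's right eye).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .palette import (
    BACKGROUND,
    CORNEA,
    FISSURE,
    LABEL_NAMES,
    MARKER,
    SKIN,
    TUMOR,
    classification_palette,
)

__all__ = [
    "SegMask",
    "EyeBox",
    "SegmentationError",
    "segment",
    "clean_mask",
    "detect_eyes",
]

#: Default number of connected components kept per label by clean_mask.
#: Sized for scenes with at most two eyes.  The FISSURE entry governs the
#: joint eye region (fissure ∪ cornea): the cornea commonly spans the full
#: fissure height and would otherwise split the fissure class in two.
DEFAULT_KEEP = {FISSURE: 2, CORNEA: 2, TUMOR: 2, MARKER: 1}

# A pixel further than this (squared RGB distance) from every palette colour
# counts as non-conforming.
_CONFORMANCE_DIST2 = 60.0**2


class SegmentationError(ValueError):
    pass


@dataclass
class SegMask:
    """Per-pixel label raster over the documented integer code set."""

    labels: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("mask must be a 2-D label raster")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise SegmentationError(f"mask contains undefined label codes {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def eye_pixels(self) -> np.ndarray:
        """Boolean raster of the interpalpebral eye region (fissure ∪ cornea)."""
        return (self.labels == FISSURE) | (self.labels == CORNEA)

    def copy(self) -> "SegMask":
        return SegMask(self.labels.copy(), list(self.warnings))


@dataclass(frozen=True)
class EyeBox:
    """Half-open pixel bounding box (x0, y0, x1, y1) with laterality."""

    x0: int
    y0: int
    x1: int
    y1: int
    laterality: str  # {"left", "right"} — the subject's eye

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise SegmentationError("degenerate eye box")
        if self.laterality not in ("left", "right"):
            raise SegmentationError(f"unknown laterality {self.laterality!r}")

    def crop(self, raster: np.ndarray) -> np.ndarray:
        return raster[self.y0 : self.y1, self.x0 : self.x1]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


def segment(image: np.ndarray, *, clean: bool = True) -> SegMask:
    """Nearest-palette-colour segmentation of a rendered scene.

    A majority-non-conforming image (one that does not resemble the documented
    palette at all) yields an all-background mask and a warning, mirroring how
    a dropped-in learned segmenter should degrade on out-of-domain input.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise SegmentationError("expected an RGB (or grayscale) raster")
    img = img[..., :3].astype(np.int32)

    colors, codes = classification_palette()
    # (H, W, N) squared distances to each reference colour.
    d2 = ((img[..., None, :] - colors[None, None, :, :].astype(np.int32)) ** 2).sum(axis=-1)
    nearest = np.argmin(d2, axis=-1)
    mindist = np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0]
    labels = codes[nearest]

    frac_bad = float((mindist > _CONFORMANCE_DIST2).mean())
    if frac_bad > 0.5:
        mask = SegMask(np.zeros(img.shape[:2], dtype=np.uint8))
        mask.warnings.append(
            f"non-conforming image ({frac_bad:.0%} of pixels far from palette); "
            "returning all-background mask"
        )
        warnings.warn(mask.warnings[-1], stacklevel=2)
        return mask

    mask = SegMask(labels)
    return clean_mask(mask) if clean else mask


def clean_mask(mask: SegMask, keep: dict[int, int] | None = None) -> SegMask:
    """Keep the K largest components per non-background class and fill holes.

    Idempotent.  Pixels dropped from a class revert to skin (or background if
    the scene has no skin at all).  Components of equal size are ranked by
    top-left raster order so the result is deterministic.
    """
    keep = {**DEFAULT_KEEP, **(keep or {})}
    labels = mask.labels
    filler = SKIN if (labels == SKIN).any() else BACKGROUND

    def largest(binary: np.ndarray, k: int) -> np.ndarray:
        comp, n = ndimage.label(binary)
        if n > k:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            # Stable tie-break: argsort is stable, components are numbered in
            # raster order, so equal sizes keep the top-left component first.
            order = np.argsort(-sizes, kind="stable")[:k] + 1
            binary = np.isin(comp, order)
        return ndimage.binary_fill_holes(binary)

    eye = (labels == FISSURE) | (labels == CORNEA)
    eye = largest(eye, keep[FISSURE]) if eye.any() else eye
    cornea = (labels == CORNEA) & eye
    cornea = largest(cornea, keep[CORNEA]) if cornea.any() else cornea

    out = np.where(labels == BACKGROUND, BACKGROUND, filler).astype(np.uint8)
    out[eye] = FISSURE
    for code in (TUMOR, MARKER):
        binary = labels == code
        if binary.any():
            out[largest(binary, keep[code])] = code
    out[cornea] = CORNEA
    return SegMask(out, list(mask.warnings))


def detect_eyes(mask: SegMask, *, margin_frac: float = 0.25) -> list[EyeBox]:
    """One bounding box per connected fissure blob, expanded and clamped.

    The box is grown by ``margin_frac`` of the blob diagonal on every side so
    downstream canthus squares have room.  Boxes are returned left to right.
    Zero fissure pixels yield an empty list; the caller decides severity.
    """
    h, w = mask.shape
    eye = mask.eye_pixels()
    comp, n = ndimage.label(eye)
    boxes: list[EyeBox] = []
    for obj_idx, sl in enumerate(ndimage.find_objects(comp), start=1):
        if sl is None:
            continue
        ys, xs = sl
        diag = float(np.hypot(ys.stop - ys.start, xs.stop - xs.start))
        pad = int(round(margin_frac * diag))
        x0 = max(0, xs.start - pad)
        y0 = max(0, ys.start - pad)
        x1 = min(w, xs.stop + pad)
        y1 = min(h, ys.stop + pad)
        cx = 0.5 * (xs.start + xs.stop)
        laterality = "right" if cx < w / 2 else "left"
        boxes.append(EyeBox(x0, y0, x1, y1, laterality))
    boxes.sort(key=lambda b: b.x0)
    return boxes
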