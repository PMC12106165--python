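"""Fiducial scale calibration and the eight morphological parameters.

All lengths are reported in millimetres via the scene's circular fiducial
marker (default 10 mm diameter), whose pixel diameter is taken as the
equivalent-circle diameter 2·sqrt(area/π) of its segmented component.

Parameters, all measured on the vertical axis column through the corneal
centre (the reproducible stand-in for the corneal light reflex of the
clinical MRD definition):

* MRD1  — corneal centre to upper lid margin (mm); negative when the margin
  crosses below the centre (severe ptosis).
* MRD2  — lower lid margin to corneal centre (mm), same sign convention.
* PF    — palpebral fissure height, defined as MRD1 + MRD2 on that column.
* corneal / lateral / medial area — visible cornea, and the fissure-minus-
  cornea region split at the axis column into temporal and nasal parts (mm²).
* upper / lower eyelid length — arc length of a quadratic fit to each margin
  chain (mm).  The fit removes the staircase bias of a rasterized polyline.

The corneal centre is estimated by a least-squares circle fit to the free
limbus arc (cornea pixels bordering the fissure), which recovers the full
disc centre even when the lids truncate the cornea; the raw component
centroid is available as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import Landmarks
from .palette import CORNEA, FISSURE, MARKER
from .segmentation import EyeBox, SegMask, clean_mask

__all__ = [
    "ScaleFactor",
    "MorphometryReport",
    "MorphometryError",
    "calibrate",
    "corneal_center",
    "compute_morphometry",
    "report_delta",
]


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleFactor:
    mm_per_px: float
    marker_px_diameter: float
    method: str = "equivalent_circle"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise MorphometryError("mm_per_px must be positive")


@dataclass
class MorphometryReport:
    """The eight calibrated parameters for one eye (lengths mm, areas mm²)."""

    mrd1_mm: float
    mrd2_mm: float
    pf_mm: float
    corneal_area_mm2: float
    lateral_area_mm2: float
    medial_area_mm2: float
    upper_lid_length_mm: float
    lower_lid_length_mm: float
    corneal_center_px: tuple[float, float]
    axis_column: int
    icd_mm: float
    timestamp: str | None = None
    warnings: list[str] = field(default_factory=list)

    _FIELDS = (
        "mrd1_mm",
        "mrd2_mm",
        "pf_mm",
        "corneal_area_mm2",
        "lateral_area_mm2",
        "medial_area_mm2",
        "upper_lid_length_mm",
        "lower_lid_length_mm",
    )

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in self._FIELDS}
        d["corneal_center_px"] = [float(v) for v in self.corneal_center_px]
        d["axis_column"] = int(self.axis_column)
        d["icd_mm"] = float(self.icd_mm)
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d


def report_delta(before: MorphometryReport, after: MorphometryReport) -> dict:
    """Parameter deltas between two visits (after − before), for monitoring."""
    return {
        name: float(getattr(after, name)) - float(getattr(before, name))
        for name in MorphometryReport._FIELDS
    }


def calibrate(
    mask: SegMask, marker_diameter_mm: float = 10.0, *, cleaned: bool = False
) -> ScaleFactor:
    """Millimetres per pixel from the circular fiducial marker.

    Uses the largest marker component after cleaning and its equivalent-circle
    diameter.  With no marker pixels, raises; pass an explicit scale instead.
    """
    work = mask if cleaned else clean_mask(mask)
    marker = work.labels == MARKER
    area = int(marker.sum())
    if area == 0:
        raise MorphometryError(
            "no marker pixels found; pass mm_per_px explicitly to skip calibration"
        )
    d_px = 2.0 * np.sqrt(area / np.pi)
    return ScaleFactor(mm_per_px=marker_diameter_mm / d_px, marker_px_diameter=d_px)


def _limbus_circle_fit(cornea: np.ndarray, fissure: np.ndarray) -> tuple[float, float] | None:
    """Kåsa least-squares circle through cornea pixels bordering the fissure."""
    border = cornea & (
        np.roll(fissure, 1, 0) | np.roll(fissure, -1, 0)
        | np.roll(fissure, 1, 1) | np.roll(fissure, -1, 1)
    )
    ys, xs = np.nonzero(border)
    if len(xs) < 6:
        return None
    a = np.column_stack([xs, ys, np.ones_like(xs)]).astype(float)
    b = (xs.astype(float) ** 2 + ys.astype(float) ** 2)
    try:
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
        return None
    return (coef[0] / 2.0, coef[1] / 2.0)


def corneal_center(
    mask: SegMask, box: EyeBox | None = None, *, method: str = "limbus_fit"
) -> tuple[float, float]:
    """Centre of the corneal disc, the per-eye MRD reference point.

    ``limbus_fit`` (default) fits a circle to the cornea/fissure boundary and
    so recovers the true disc centre under partial lid occlusion; ``centroid``
    returns the visible-component centroid, which drifts toward the exposed
    part of a truncated disc (documented behaviour, kept for comparison).
    """
    labels = box.crop(mask.labels) if box is not None else mask.labels
    cornea = labels == CORNEA
    if not cornea.any():
        raise MorphometryError("no cornea pixels; cornea fully occluded?")
    cy, cx = ndimage.center_of_mass(cornea)
    if method == "limbus_fit":
        fit = _limbus_circle_fit(cornea, labels == FISSURE)
        if fit is not None:
            cx, cy = fit
    elif method != "centroid":
        raise MorphometryError(f"unknown corneal_center method {method!r}")
    if box is not None:
        cx += box.x0
        cy += box.y0
    return (float(cx), float(cy))


def _quadratic_arc_length(a: float, b: float, x0: float, x1: float) -> float:
    """Closed-form arc length of y = a·x² + b·x + c over [x0, x1]."""
    if abs(a) < 1e-12:
        return float(np.hypot(1.0, b) * abs(x1 - x0))

    def antider(u: float) -> float:
        return 0.5 * (u * np.sqrt(1.0 + u * u) + np.arcsinh(u))

    u0, u1 = 2 * a * x0 + b, 2 * a * x1 + b
    return float(abs((antider(u1) - antider(u0)) / (2 * a)))


def _margin_length_px(chain: np.ndarray) -> float:
    xs = chain[:, 0].astype(float)
    ys = chain[:, 1].astype(float)
    if len(xs) < 3 or np.ptp(xs) < 2:
        # Degenerate span: fall back to the raw polyline length.
        return float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
    a, b, _c = np.polyfit(xs, ys, 2)
    return _quadratic_arc_length(float(a), float(b), xs.min(), xs.max())


def compute_morphometry(
    mask: SegMask,
    lm: Landmarks,
    scale: ScaleFactor,
    *,
    box: EyeBox | None = None,
    center: tuple[float, float] | None = None,
) -> MorphometryReport:
    """The eight parameters for one eye.

    The axis column is the corneal-centre column rounded to the nearest pixel
    column; MRD1/MRD2/PF are measured there.  The area partition is
    pixel-exact: lateral + medial + visible-cornea = total eye-region area,
    with axis-column pixels assigned to the medial (nasal) side.
    """
    s = scale.mm_per_px
    if center is None:
        center = corneal_center(mask, box)
    cx, cy = center
    axis = int(round(cx))

    y_up = lm.margin_y_at(axis, "upper")  # raises if axis outside fissure span
    y_lo = lm.margin_y_at(axis, "lower")
    mrd1 = (cy - y_up) * s
    mrd2 = (y_lo - cy) * s
    pf = mrd1 + mrd2

    labels = box.crop(mask.labels) if box is not None else mask.labels
    x_offset = box.x0 if box is not None else 0
    cornea = labels == CORNEA
    fissure_only = labels == FISSURE
    corneal_area = float(cornea.sum()) * s * s

    cols = np.arange(labels.shape[1]) + x_offset
    nasal_is_larger_x = lm.inner_canthus[0] > lm.outer_canthus[0]
    medial_cols = cols >= axis if nasal_is_larger_x else cols <= axis
    medial_area = float(fissure_only[:, medial_cols].sum()) * s * s
    lateral_area = float(fissure_only[:, ~medial_cols].sum()) * s * s

    return MorphometryReport(
        mrd1_mm=mrd1,
        mrd2_mm=mrd2,
        pf_mm=pf,
        corneal_area_mm2=corneal_area,
        lateral_area_mm2=lateral_area,
        medial_area_mm2=medial_area,
        upper_lid_length_mm=_margin_length_px(lm.upper_margin) * s,
        lower_lid_length_mm=_margin_length_px(lm.lower_margin) * s,
        corneal_center_px=(cx, cy),
        axis_column=axis,
        icd_mm=lm.icd_px * s,
    )
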