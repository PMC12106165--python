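"""Seeded parametric generator of eye scenes with exact ground truth.

The generator emulates the photographic protocol behind the screening
pipeline — primary gaze, frontal standardized framing, a 10 mm circular
fiducial on the forehead — at cartoon fidelity: flat palette colours, lid
margins as quadratic arcs through the two canthi, the cornea as a disc
clipped to the interpalpebral fissure, pathology rendered as deterministic
margin/canthus textures, and optional additive Gaussian intensity noise.

Every scene carries analytic ground truth computed from the parameters by
closed-form geometry and adaptive quadrature — never from pixels — so each
downstream stage can be tested against exact expected values: the eight
morphological parameters (``truth_report``), the generator-implied findings,
and the disease set the atlas assigns to them (``truth_diagnoses``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import integrate, optimize

from . import abnormality, atlas
from .abnormality import Finding, Thresholds
from .morphometry import MorphometryReport
from .palette import (
    CORNEA,
    ECTROPION_COLOR,
    FISSURE,
    FOLD_COLOR,
    LASH_COLOR,
    MARKER,
    PALETTE,
    SKIN,
    TUMOR,
)
from .segmentation import SegMask

__all__ = [
    "EyeSceneParams",
    "EyeTruth",
    "EyeScene",
    "SceneValidationError",
    "generate_scene",
    "generate_binocular",
    "params_for_condition",
    "generate_cohort",
    "supported_conditions",
    "expected_diagnoses",
    "scene_templates",
    "save_scene",
]

_FOLD_TYPES = ("none", "epicanthus_inversus", "epicanthus_other")


class SceneValidationError(ValueError):
    pass


@dataclass(frozen=True)
class EyeSceneParams:
    """Generative ground truth for one eye plus the shared fiducial marker."""

    image_size: tuple[int, int]  # (height, width) px
    laterality: str  # subject's eye: {"left", "right"}
    inner_canthus: tuple[int, int]  # (x, y) px
    outer_canthus: tuple[int, int]
    upper_curve_peak_mm: float  # apex height of the upper margin above the chord
    lower_curve_dip_mm: float  # depth of the lower margin below the chord
    cornea_center: tuple[float, float]  # (x, y) px
    cornea_radius_mm: float
    fold_type: str = "none"
    fold_extent_mm: float = 2.0
    entropion_flag: bool = False
    trichiasis_flag: bool = False
    ectropion_flag: bool = False
    tumor_center: tuple[float, float] | None = None
    tumor_radius_mm: float | None = None
    marker_center: tuple[int, int] = (48, 220)  # (y, x) px
    marker_diameter_mm: float = 10.0
    mm_per_px: float = 0.2
    noise_sd: float = 3.0
    seed: int = 0
    condition: str | None = None  # metadata: the template this was drawn from

    # -- derived pixel geometry -------------------------------------------
    @property
    def chord_y(self) -> int:
        return self.inner_canthus[1]

    @property
    def x_left(self) -> int:
        return min(self.inner_canthus[0], self.outer_canthus[0])

    @property
    def x_right(self) -> int:
        return max(self.inner_canthus[0], self.outer_canthus[0])

    @property
    def icd_px(self) -> float:
        return float(self.x_right - self.x_left)

    @property
    def icd_mm(self) -> float:
        return self.icd_px * self.mm_per_px

    def margin_y(self, x, which: str):
        """Analytic margin ordinate: quadratic arc through both canthi."""
        x = np.asarray(x, dtype=float)
        span = self.icd_px
        t = (x - self.x_left) / span
        bump = 4.0 * t * (1.0 - t)
        if which == "upper":
            return self.chord_y - (self.upper_curve_peak_mm / self.mm_per_px) * bump
        return self.chord_y + (self.lower_curve_dip_mm / self.mm_per_px) * bump

    def validate(self) -> None:
        h, w = self.image_size
        if self.mm_per_px <= 0:
            raise SceneValidationError("violated invariant: mm_per_px > 0")
        if self.laterality not in ("left", "right"):
            raise SceneValidationError(f"unknown laterality {self.laterality!r}")
        if self.fold_type not in _FOLD_TYPES:
            raise SceneValidationError(f"unknown fold_type {self.fold_type!r}")
        if self.inner_canthus[1] != self.outer_canthus[1]:
            raise SceneValidationError(
                "violated invariant: canthi must lie on the same horizontal band"
            )
        for name, (x, y) in (("inner_canthus", self.inner_canthus),
                             ("outer_canthus", self.outer_canthus)):
            if not (0 <= x < w and 0 <= y < h):
                raise SceneValidationError(f"violated invariant: {name} inside the image")
        if self.icd_px <= 0:
            raise SceneValidationError("violated invariant: distinct canthus columns")
        cx, cy = self.cornea_center
        if not (self.margin_y(cx, "upper") < cy < self.margin_y(cx, "lower")):
            raise SceneValidationError(
                "violated invariant: cornea_center between the lid curves"
            )
        top_margin = self.chord_y - self.upper_curve_peak_mm / self.mm_per_px
        bottom_margin = self.chord_y + self.lower_curve_dip_mm / self.mm_per_px
        if top_margin < 0 or bottom_margin >= h:
            raise SceneValidationError("violated invariant: lid curves inside the image")
        my, mx = self.marker_center
        r_marker = 0.5 * self.marker_diameter_mm / self.mm_per_px
        if not (r_marker <= my < h - r_marker and r_marker <= mx < w - r_marker):
            raise SceneValidationError("violated invariant: marker inside the image")
        # Marker disjoint from the eye region (with a small guard band).
        pad = 4
        if (my + r_marker >= top_margin - pad - 6
                and my - r_marker <= bottom_margin + pad
                and mx + r_marker >= self.x_left - pad
                and mx - r_marker <= self.x_right + pad):
            raise SceneValidationError(
                "violated invariant: marker region disjoint from the eye region"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EyeSceneParams":
        d = dict(d)
        for key in ("image_size", "inner_canthus", "outer_canthus", "cornea_center",
                    "marker_center"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("tumor_center") is not None:
            d["tumor_center"] = tuple(d["tumor_center"])
        return cls(**d)


@dataclass
class EyeTruth:
    """Analytic ground truth for one rendered eye."""

    params: EyeSceneParams
    report: MorphometryReport
    findings: list[Finding]
    diagnoses: set[str]


@dataclass
class EyeScene:
    """A rendered scene: image, label mask, and per-eye analytic truth."""

    image: np.ndarray
    mask: SegMask
    eyes: list[EyeTruth]
    condition: str | None = None

    # Single-eye conveniences
    @property
    def params(self) -> EyeSceneParams:
        return self.eyes[0].params

    @property
    def truth_report(self) -> MorphometryReport:
        return self.eyes[0].report

    @property
    def truth_findings(self) -> list[Finding]:
        return self.eyes[0].findings

    @property
    def truth_diagnoses(self) -> set[str]:
        return self.eyes[0].diagnoses


# ---------------------------------------------------------------------------
# Analytic ground truth

def _visible_cornea_bounds(p: EyeSceneParams, x: float) -> float:
    cx, cy = p.cornea_center
    r = p.cornea_radius_mm / p.mm_per_px
    g = np.sqrt(max(0.0, r * r - (x - cx) ** 2))
    top = max(float(p.margin_y(x, "upper")), cy - g)
    bot = min(float(p.margin_y(x, "lower")), cy + g)
    return max(0.0, bot - top)


def _integrate_with_breaks(fn, lo: float, hi: float, candidates) -> float:
    """Adaptive quadrature with breakpoints at the integrand's kinks."""
    if hi <= lo:
        return 0.0
    pts = sorted(p for p in candidates if lo < p < hi)
    val, _err = integrate.quad(fn, lo, hi, points=pts or None, limit=200)
    return float(val)


def _kink_points(p: EyeSceneParams, lo: float, hi: float) -> list[float]:
    """Where the cornea circle meets either lid parabola (clipping kinks)."""
    cx, cy = p.cornea_center
    r = p.cornea_radius_mm / p.mm_per_px
    pts = [cx - r, cx + r]
    for which, sign in (("upper", -1.0), ("lower", 1.0)):
        def h(x, which=which, sign=sign):
            g2 = r * r - (x - cx) ** 2
            if g2 < 0:
                return np.nan
            return float(p.margin_y(x, which)) - (cy + sign * np.sqrt(g2))

        grid = np.linspace(max(lo, cx - r) + 1e-9, min(hi, cx + r) - 1e-9, 400)
        vals = np.array([h(x) for x in grid])
        sgn = np.sign(vals)
        for i in np.flatnonzero(np.diff(sgn) != 0):
            try:
                pts.append(float(optimize.brentq(h, grid[i], grid[i + 1])))
            except ValueError:  # pragma: no cover - flat sign artefact
                pass
    return pts


def _arc_length_px(p: EyeSceneParams, which: str) -> float:
    h_px = (p.upper_curve_peak_mm if which == "upper" else p.lower_curve_dip_mm) / p.mm_per_px
    span = p.icd_px

    def dydx(x):
        t = (x - p.x_left) / span
        return 4.0 * h_px * (1.0 - 2.0 * t) / span

    val, _ = integrate.quad(lambda x: np.hypot(1.0, dydx(x)), p.x_left, p.x_right,
                            limit=200)
    return float(val)


def truth_morphometry(p: EyeSceneParams) -> MorphometryReport:
    """The eight parameters from closed-form geometry and quadrature."""
    s = p.mm_per_px
    cx, cy = p.cornea_center
    mrd1 = (cy - float(p.margin_y(cx, "upper"))) * s
    mrd2 = (float(p.margin_y(cx, "lower")) - cy) * s

    xl, xr = float(p.x_left), float(p.x_right)
    kinks = _kink_points(p, xl, xr)
    cornea_px2 = _integrate_with_breaks(
        lambda x: _visible_cornea_bounds(p, x), xl, xr, kinks
    )

    def fissure_height(x):
        return float(p.margin_y(x, "lower")) - float(p.margin_y(x, "upper"))

    def fissure_minus_cornea(x):
        return fissure_height(x) - _visible_cornea_bounds(p, x)

    nasal_is_larger_x = p.inner_canthus[0] > p.outer_canthus[0]
    med_lo, med_hi = (cx, xr) if nasal_is_larger_x else (xl, cx)
    lat_lo, lat_hi = (xl, cx) if nasal_is_larger_x else (cx, xr)
    medial_px2 = _integrate_with_breaks(fissure_minus_cornea, med_lo, med_hi, kinks)
    lateral_px2 = _integrate_with_breaks(fissure_minus_cornea, lat_lo, lat_hi, kinks)

    return MorphometryReport(
        mrd1_mm=mrd1,
        mrd2_mm=mrd2,
        pf_mm=mrd1 + mrd2,
        corneal_area_mm2=cornea_px2 * s * s,
        lateral_area_mm2=lateral_px2 * s * s,
        medial_area_mm2=medial_px2 * s * s,
        upper_lid_length_mm=_arc_length_px(p, "upper") * s,
        lower_lid_length_mm=_arc_length_px(p, "lower") * s,
        corneal_center_px=(cx, cy),
        axis_column=int(round(cx)),
        icd_mm=p.icd_mm,
    )


def truth_findings(p: EyeSceneParams, th: Thresholds | None = None) -> list[Finding]:
    """Findings implied analytically by the parameters under the thresholds."""
    th = th or Thresholds()
    report = truth_morphometry(p)
    findings = abnormality.detect_parametric(report, th)
    if p.entropion_flag or p.trichiasis_flag:
        findings.append(Finding("upper_eyelid", "entropion_trichiasis", 0.95,
                                {"generator": "margin texture"}))
    if p.ectropion_flag:
        findings.append(Finding("lower_eyelid", "ectropion", 0.95,
                                {"generator": "margin texture"}))
    if p.fold_type != "none":
        findings.append(Finding("inner_canthus", p.fold_type, 0.95,
                                {"generator": "fold texture"}))
    if p.tumor_radius_mm is not None:
        area = float(np.pi * p.tumor_radius_mm**2)
        if area >= th.tumor_min_area_mm2:
            findings.append(Finding("lower_eyelid", "tumor", 0.95,
                                    {"lesion_area_mm2": area}))
    return findings


# ---------------------------------------------------------------------------
# Rendering

def _render_eye(mask: np.ndarray, p: EyeSceneParams) -> None:
    h, w = mask.shape
    xl, xr = p.x_left, p.x_right
    cols = np.arange(xl, xr + 1)
    y_up = np.asarray(p.margin_y(cols, "upper"))
    y_lo = np.asarray(p.margin_y(cols, "lower"))

    r0 = max(0, int(np.floor(y_up.min())))
    r1 = min(h, int(np.ceil(y_lo.max())) + 1)
    rows = np.arange(r0, r1)
    inside = (rows[:, None] >= y_up[None, :]) & (rows[:, None] <= y_lo[None, :])
    sub = mask[r0:r1, xl : xr + 1]
    sub[inside] = FISSURE

    cx, cy = p.cornea_center
    r_px = p.cornea_radius_mm / p.mm_per_px
    dx = cols[None, :] - cx
    dy = rows[:, None] - cy
    disc = dx * dx + dy * dy <= r_px * r_px
    sub[inside & disc] = CORNEA

    if p.tumor_center is not None and p.tumor_radius_mm is not None:
        tx, ty = p.tumor_center
        rt = p.tumor_radius_mm / p.mm_per_px
        yy, xx = np.mgrid[0:h, 0:w]
        tdisc = (xx - tx) ** 2 + (yy - ty) ** 2 <= rt * rt
        mask[tdisc & (mask == SKIN)] = TUMOR


def _paint_textures(image: np.ndarray, mask: np.ndarray, p: EyeSceneParams) -> None:
    """Deterministic pathology textures, drawn over skin pixels only."""
    h, w = mask.shape
    xl, xr = p.x_left, p.x_right
    cols = np.arange(xl, xr + 1)
    y_up = np.asarray(p.margin_y(cols, "upper"))
    y_lo = np.asarray(p.margin_y(cols, "lower"))

    def paint(rr, cc, color):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[ok], cc[ok]
        skin = mask[rr, cc] == SKIN
        image[rr[skin], cc[skin]] = color

    if p.entropion_flag or p.trichiasis_flag:
        # Inward-turned lash strokes just above the upper margin.
        for i in range(2, len(cols) - 2, 3):
            top = int(np.ceil(y_up[i]))
            rr = np.arange(top - 5, top)
            paint(rr, np.full_like(rr, cols[i]), LASH_COLOR)
    if p.ectropion_flag:
        # Everted tarsal band along the lower margin.
        for i in range(1, len(cols) - 1):
            bot = int(np.floor(y_lo[i]))
            rr = np.arange(bot + 1, bot + 5)
            paint(rr, np.full_like(rr, cols[i]), ECTROPION_COLOR)
    if p.fold_type != "none":
        # Skin-fold band medial to the inner canthus; an inversus fold rises
        # from the lower lid (below the canthus), other folds hang from above.
        x_in, y_in = p.inner_canthus
        direction = 1 if p.inner_canthus[0] > p.outer_canthus[0] else -1
        extent_px = max(3, int(round(p.fold_extent_mm / p.mm_per_px)))
        band_h = max(8, int(round(1.8 * extent_px)))
        cc = x_in + direction * np.arange(1, extent_px + 1)
        if p.fold_type == "epicanthus_inversus":
            rr = np.arange(y_in + 1, y_in + 1 + band_h)
        else:
            rr = np.arange(y_in - band_h, y_in)
        rr_grid, cc_grid = np.meshgrid(rr, cc, indexing="ij")
        paint(rr_grid.ravel(), cc_grid.ravel(), FOLD_COLOR)


def _render(params_list: list[EyeSceneParams], condition: str | None = None) -> EyeScene:
    first = params_list[0]
    for p in params_list:
        p.validate()
        if p.image_size != first.image_size or p.mm_per_px != first.mm_per_px:
            raise SceneValidationError("all eyes must share canvas and scale")
        if p.marker_center != first.marker_center:
            raise SceneValidationError("all eyes must share the fiducial marker")
    for a, b in zip(params_list, params_list[1:]):
        if not (a.x_right + 2 < b.x_left or b.x_right + 2 < a.x_left):
            raise SceneValidationError(
                "violated invariant: eye regions must be horizontally disjoint"
            )
    h, w = first.image_size
    mask = np.full((h, w), SKIN, dtype=np.uint8)

    my, mx = first.marker_center
    r_marker = 0.5 * first.marker_diameter_mm / first.mm_per_px
    yy, xx = np.mgrid[0:h, 0:w]
    mask[(xx - mx) ** 2 + (yy - my) ** 2 <= r_marker * r_marker] = MARKER

    for p in params_list:
        _render_eye(mask, p)

    palette = np.zeros((max(PALETTE) + 1, 3), dtype=np.uint8)
    for code, color in PALETTE.items():
        palette[code] = color
    image = palette[mask].astype(np.float64)
    for p in params_list:
        _paint_textures(image, mask, p)

    if first.noise_sd > 0:
        rng = np.random.default_rng(first.seed)
        image = image + rng.normal(0.0, first.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    eyes = []
    for p in params_list:
        report = truth_morphometry(p)
        findings = truth_findings(p)
        diagnoses = atlas.apply_atlas(findings, report, atlas.default_rules()).diseases
        eyes.append(EyeTruth(params=p, report=report, findings=findings,
                             diagnoses=diagnoses))
    return EyeScene(image=image, mask=SegMask(mask), eyes=eyes, condition=condition)


def generate_scene(params: EyeSceneParams, *, condition: str | None = None) -> EyeScene:
    """Render one eye scene; deterministic and bit-identical given params."""
    return _render([params], condition=condition or params.condition)


def generate_binocular(right: EyeSceneParams, left: EyeSceneParams) -> EyeScene:
    """Render a two-eye scene sharing one canvas and fiducial marker."""
    if right.laterality == left.laterality:
        raise SceneValidationError("binocular scene needs one eye of each laterality")
    return _render([right, left])


def binocular_params(
    condition_right: str, condition_left: str, seed: int
) -> tuple[EyeSceneParams, EyeSceneParams]:
    """Per-eye parameters for a two-eye scene on a wide shared canvas.

    The subject's right eye sits in the left image half and vice versa,
    matching the frontal-photo laterality convention.
    """
    size = (300, 880)
    marker = (48, 440)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    right = params_for_condition(
        condition_right, int(seeds[0]), laterality="right",
        image_size=size, eye_center_x=220, marker_center=marker,
    )
    left = params_for_condition(
        condition_left, int(seeds[1]), laterality="left",
        image_size=size, eye_center_x=660, marker_center=marker,
    )
    return right, left


# ---------------------------------------------------------------------------
# Condition templates

def scene_templates() -> dict:
    text = resources.files("lidmorph").joinpath("data/scene_templates.yaml").read_text()
    return yaml.safe_load(text)


def supported_conditions() -> list[str]:
    doc = scene_templates()
    return sorted(set(doc["conditions"]) | set(doc["aliases"]) | {"normal"})


def expected_diagnoses(condition: str) -> set[str]:
    """The disease set a condition template is built to produce."""
    table = {
        "normal": set(),
        "ptosis": {"blepharoptosis"},
        "blepharoptosis": {"blepharoptosis"},
        "upper_retraction": {"tao"},
        "lower_retraction": {"tao"},
        "tao": {"tao"},
        "ectropion": {"ectropion"},
        "entropion_trichiasis": {"entropion_and_trichiasis"},
        "entropion_and_trichiasis": {"entropion_and_trichiasis"},
        "tumor": {"eyelid_tumor"},
        "eyelid_tumor": {"eyelid_tumor"},
        "epicanthus_inversus": {"epicanthus_inversus"},
        "epicanthus_other": {"epicanthus_other"},
        "bpes": {"bpes"},
        "blepharoptosis_trichiasis": {"blepharoptosis", "entropion_and_trichiasis"},
        "blepharoptosis_epicanthus_other": {"blepharoptosis", "epicanthus_other"},
        "blepharoptosis_ectropion": {"blepharoptosis", "ectropion"},
    }
    if condition not in table:
        raise SceneValidationError(
            f"unknown condition {condition!r}; supported: {supported_conditions()}"
        )
    return set(table[condition])


def _sample(rng: np.random.Generator, value):
    if isinstance(value, (list, tuple)) and len(value) == 2 and all(
        isinstance(v, (int, float)) for v in value
    ):
        return float(rng.uniform(value[0], value[1]))
    return value


def params_for_condition(
    condition: str,
    seed: int,
    *,
    laterality: str | None = None,
    image_size: tuple[int, int] | None = None,
    eye_center_x: float | None = None,
    marker_center: tuple[int, int] | None = None,
) -> EyeSceneParams:
    """Jittered parameters for a supported condition (or disease alias).

    The canvas/placement overrides exist for multi-eye composition; the
    defaults produce a monocular scene.
    """
    doc = scene_templates()
    key = doc["aliases"].get(condition, condition)
    if key not in doc["conditions"]:
        raise SceneValidationError(
            f"unknown condition {condition!r}; supported: {supported_conditions()}"
        )
    cfg = dict(doc["base"])
    cfg.update(doc["conditions"][key] or {})
    if image_size is not None:
        cfg["image_size"] = list(image_size)
    if marker_center is not None:
        cfg["marker_center_px"] = list(marker_center)

    rng = np.random.default_rng(seed)
    lat = laterality or ("right" if rng.random() < 0.5 else "left")
    h, w = cfg["image_size"]
    s = cfg["mm_per_px"]
    icd_px = _sample(rng, cfg["icd_mm"]) / s
    if eye_center_x is None:
        center_x = w / 2 + (
            -cfg["eye_offset_px"] if lat == "right" else cfg["eye_offset_px"]
        )
    else:
        center_x = float(eye_center_x)
    center_x += rng.uniform(-5, 5)
    chord_y = int(cfg["chord_y_px"] + rng.integers(-6, 7))
    x_lo = int(round(center_x - icd_px / 2))
    x_hi = int(round(center_x + icd_px / 2))
    # Nasal side faces the image midline.
    inner = (x_hi, chord_y) if lat == "right" else (x_lo, chord_y)
    outer = (x_lo, chord_y) if lat == "right" else (x_hi, chord_y)

    peak = _sample(rng, cfg["upper_peak_mm"])
    dip = _sample(rng, cfg["lower_dip_mm"])
    height = _sample(rng, cfg["cornea_height_mm"])
    cornea_cx = (x_lo + x_hi) / 2 + _sample(rng, cfg["cornea_dx_mm"]) / s
    cornea = (cornea_cx, chord_y - height / s)

    tumor_center = None
    tumor_radius = None
    if cfg.get("tumor_radius_mm"):
        tumor_radius = _sample(rng, cfg["tumor_radius_mm"])
        tx = (x_lo + x_hi) / 2 + rng.uniform(-15, 15)
        ty = chord_y + dip / s + 5 + tumor_radius / s + 1
        tumor_center = (float(tx), float(ty))

    return EyeSceneParams(
        image_size=(h, w),
        laterality=lat,
        inner_canthus=inner,
        outer_canthus=outer,
        upper_curve_peak_mm=peak,
        lower_curve_dip_mm=dip,
        cornea_center=cornea,
        cornea_radius_mm=_sample(rng, cfg["cornea_radius_mm"]),
        fold_type=cfg["fold_type"],
        fold_extent_mm=_sample(rng, cfg["fold_extent_mm"]),
        entropion_flag=bool(cfg["entropion_flag"]),
        trichiasis_flag=bool(cfg["trichiasis_flag"]),
        ectropion_flag=bool(cfg["ectropion_flag"]),
        tumor_center=tumor_center,
        tumor_radius_mm=tumor_radius,
        marker_center=tuple(cfg["marker_center_px"]),
        marker_diameter_mm=float(cfg["marker_diameter_mm"]),
        mm_per_px=float(s),
        noise_sd=float(cfg["noise_sd"]),
        seed=int(seed),
        condition=condition,
    )


def generate_cohort(class_mix: dict[str, int], seed: int) -> list[EyeScene]:
    """A seeded cohort of single-eye scenes; deterministic given the seed."""
    for label, count in class_mix.items():
        if count < 0:
            raise SceneValidationError(f"negative count for {label!r}")
        expected_diagnoses(label)  # validates the label early
    rng = np.random.default_rng(seed)
    scenes = []
    for label, count in class_mix.items():
        for _ in range(count):
            child = int(rng.integers(0, 2**31 - 1))
            params = params_for_condition(label, child)
            scenes.append(generate_scene(params, condition=label))
    return scenes


def save_scene(scene: EyeScene, out_dir, stem: str) -> dict[str, str]:
    """Write image PNG, mask PNG, and a JSON sidecar with params and truth."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.png"
    mask_path = out / f"{stem}_mask.png"
    json_path = out / f"{stem}.json"
    iio.imwrite(img_path, scene.image)
    iio.imwrite(mask_path, scene.mask.labels)
    sidecar = {
        "condition": scene.condition,
        "eyes": [
            {
                "params": t.params.to_dict(),
                "truth_report": t.report.to_dict(),
                "truth_findings": [f.to_dict() for f in t.findings],
                "truth_diagnoses": sorted(t.diagnoses),
            }
            for t in scene.eyes
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"image": str(img_path), "mask": str(mask_path), "sidecar": str(json_path)}
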