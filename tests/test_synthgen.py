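"""Generator: determinism, label exclusivity, analytic truth, templates."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from lidmorph import segmentation, synthgen
from lidmorph.palette import LABEL_NAMES, MARKER, TUMOR
from lidmorph.synthgen import (
    EyeSceneParams,
    SceneValidationError,
    expected_diagnoses,
    generate_cohort,
    params_for_condition,
    supported_conditions,
    truth_morphometry,
)


# ---------------------------------------------------------------------------
# Independent analytic oracle: recompute the truth report from first
# principles (closed-form margins, quartic circle/parabola intersections,
# piecewise quadrature) without touching the generator's truth code paths.

def _margin_poly(p: EyeSceneParams, which: str):
    """Margin as a numpy Polynomial in x (independent derivation)."""
    h_px = (p.upper_curve_peak_mm if which == "upper" else p.lower_curve_dip_mm) / p.mm_per_px
    sign = -1.0 if which == "upper" else 1.0
    span = p.icd_px
    xl = p.x_left
    # y(x) = chord + sign*4h*t(1-t),  t=(x-xl)/L
    u = np.polynomial.Polynomial([-xl, 1.0])  # x - xl
    t = u / span
    return p.chord_y + sign * 4.0 * h_px * t * (1.0 - t)


def oracle_truth(p: EyeSceneParams) -> dict:
    s = p.mm_per_px
    cx, cy = p.cornea_center
    r = p.cornea_radius_mm / s
    up = _margin_poly(p, "upper")
    lo = _margin_poly(p, "lower")
    mrd1 = (cy - up(cx)) * s
    mrd2 = (lo(cx) - cy) * s

    # Circle/parabola intersections via quartic roots.
    breaks = {cx - r, cx + r}
    xc = np.polynomial.Polynomial([-cx, 1.0])
    for poly, sign in ((up, -1.0), (lo, 1.0)):
        quartic = xc * xc + (poly - cy) ** 2 - r * r
        for root in quartic.roots():
            if abs(root.imag) < 1e-9 and p.x_left < root.real < p.x_right:
                x = float(root.real)
                g2 = r * r - (x - cx) ** 2
                if g2 >= -1e-9:
                    branch = cy + sign * np.sqrt(max(0.0, g2))
                    if abs(poly(x) - branch) < 1e-6:
                        breaks.add(round(x, 12))

    def visible(x):
        g2 = r * r - (x - cx) ** 2
        if g2 <= 0:
            return 0.0
        g = np.sqrt(g2)
        return max(0.0, min(lo(x), cy + g) - max(up(x), cy - g))

    def piecewise(fn, lo_x, hi_x):
        pts = [lo_x] + sorted(b for b in breaks if lo_x < b < hi_x) + [hi_x]
        return sum(
            integrate.quad(fn, a, b, limit=200)[0] for a, b in zip(pts, pts[1:])
        )

    xl, xr = float(p.x_left), float(p.x_right)
    cornea_area = piecewise(visible, xl, xr) * s * s

    def sliver(x):
        return (lo(x) - up(x)) - visible(x)

    nasal_larger = p.inner_canthus[0] > p.outer_canthus[0]
    med = piecewise(sliver, cx, xr) if nasal_larger else piecewise(sliver, xl, cx)
    lat = piecewise(sliver, xl, cx) if nasal_larger else piecewise(sliver, cx, xr)

    def arclen(poly):
        d = poly.deriv()
        return integrate.quad(lambda x: np.hypot(1.0, d(x)), xl, xr, limit=200)[0]

    return {
        "mrd1_mm": mrd1,
        "mrd2_mm": mrd2,
        "pf_mm": mrd1 + mrd2,
        "corneal_area_mm2": cornea_area,
        "medial_area_mm2": med * s * s,
        "lateral_area_mm2": lat * s * s,
        "upper_lid_length_mm": arclen(up) * s,
        "lower_lid_length_mm": arclen(lo) * s,
    }


def test_truth_report_matches_independent_geometry_oracle():
    """Analytic truth equals a from-scratch geometric recomputation to 1e-9."""
    for seed in range(50):
        p = params_for_condition("normal", 7000 + seed)
        truth = truth_morphometry(p)
        expect = oracle_truth(p)
        for key, val in expect.items():
            assert getattr(truth, key) == pytest.approx(val, abs=1e-9), key


def test_scene_is_deterministic_and_noise_only_touches_intensities(normal_params):
    a = synthgen.generate_scene(normal_params)
    b = synthgen.generate_scene(normal_params)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask.labels, b.mask.labels)

    other = synthgen.generate_scene(replace(normal_params, seed=normal_params.seed + 1))
    assert not np.array_equal(a.image, other.image)
    assert np.array_equal(a.mask.labels, other.mask.labels)


def test_mask_labels_exclusive_and_in_code_set(normal_scene):
    labels = normal_scene.mask.labels
    assert set(np.unique(labels)) <= set(LABEL_NAMES)
    # one label per pixel by construction; eye blobs bounded by two
    from scipy import ndimage

    assert ndimage.label(normal_scene.mask.eye_pixels())[1] <= 2


def test_marker_renders_at_calibrated_pixel_diameter(normal_scene):
    # 10 mm at 0.2 mm/px -> equivalent-circle diameter 50 px
    area = int((normal_scene.mask.labels == MARKER).sum())
    d_px = 2 * np.sqrt(area / np.pi)
    assert d_px == pytest.approx(50.0, abs=0.5)


def test_trivial_pf_by_construction():
    # upper peak 4 mm + lower dip 1 mm with the cornea on the fissure-centre
    # column: the rendered vertical gap there is 5 mm by construction.
    p = params_for_condition("normal", 3, laterality="right")
    p = replace(
        p,
        upper_curve_peak_mm=4.0,
        lower_curve_dip_mm=1.0,
        cornea_center=((p.x_left + p.x_right) / 2, p.chord_y - 2.0 / p.mm_per_px),
    )
    truth = truth_morphometry(p)
    assert truth.pf_mm == pytest.approx(5.0, abs=1e-12)


@pytest.mark.parametrize("condition", sorted(supported_conditions()))
def test_condition_templates_satisfy_their_defining_predicates(condition):
    """50 seeded parameter draws per label all satisfy the label's geometry."""
    for seed in range(50):
        p = params_for_condition(condition, 1000 + seed)
        p.validate()
        truth = truth_morphometry(p)
        expected = expected_diagnoses(condition)
        # Jitter margin of 0.25 mm against the screening thresholds.
        if "blepharoptosis" in expected or condition in ("ptosis", "bpes"):
            assert truth.mrd1_mm < 2.0 - 0.25
        if condition in ("upper_retraction", "tao"):
            assert truth.mrd1_mm > 5.0 + 0.25
        if condition == "lower_retraction":
            assert truth.mrd2_mm > 5.5 + 0.25
        if condition == "normal":
            assert 2.0 + 0.25 < truth.mrd1_mm < 5.0 - 0.25
            assert truth.mrd2_mm < 5.5 - 0.25
        if condition in ("bpes",):
            assert truth.icd_mm < 30.0 - 1.0
            assert p.fold_type == "epicanthus_inversus"
        if condition in ("epicanthus_inversus",):
            assert p.fold_type == "epicanthus_inversus"
        if condition in ("epicanthus_other", "blepharoptosis_epicanthus_other"):
            assert p.fold_type == "epicanthus_other"
        if condition in ("tumor", "eyelid_tumor"):
            assert np.pi * p.tumor_radius_mm**2 > 1.0 + 0.5
        if condition in ("ectropion", "blepharoptosis_ectropion"):
            assert p.ectropion_flag
        if condition in ("entropion_trichiasis", "entropion_and_trichiasis",
                         "blepharoptosis_trichiasis"):
            assert p.entropion_flag or p.trichiasis_flag
        # Implied diagnosis set always matches the registry.
        assert synthgen.truth_findings(p) is not None
        scene_diag = synthgen.atlas.apply_atlas(
            synthgen.truth_findings(p), truth, synthgen.atlas.default_rules()
        ).diseases
        assert scene_diag == expected


def test_unknown_condition_lists_supported_labels():
    with pytest.raises(SceneValidationError, match="supported"):
        params_for_condition("dermatochalasis", 0)


@pytest.mark.parametrize(
    "mutation, message",
    [
        (lambda p: replace(p, inner_canthus=(-5, p.chord_y),
                           outer_canthus=(p.outer_canthus[0], p.chord_y)),
         "inside the image"),
        (lambda p: replace(p, cornea_center=(p.cornea_center[0], p.chord_y - 90)),
         "between the lid curves"),
        (lambda p: replace(p, marker_center=(p.chord_y, p.inner_canthus[0])),
         "disjoint"),
        (lambda p: replace(p, mm_per_px=0.0), "mm_per_px"),
        (lambda p: replace(p, inner_canthus=(p.inner_canthus[0], p.chord_y + 3)),
         "horizontal band"),
    ],
)
def test_invalid_geometry_rejected_with_named_invariant(normal_params, mutation, message):
    with pytest.raises(SceneValidationError, match=message):
        synthgen.generate_scene(mutation(normal_params))


def test_cohort_counts_determinism_and_empty():
    mix = {"normal": 3, "eyelid_tumor": 2}
    a = generate_cohort(mix, seed=7)
    b = generate_cohort(mix, seed=7)
    assert len(a) == 5
    assert sum((s.mask.labels == TUMOR).any() for s in a) == 2
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.image, sb.image)
    assert generate_cohort({}, seed=7) == []
    with pytest.raises(SceneValidationError):
        generate_cohort({"normal": -1}, seed=7)


def test_binocular_scene_has_two_opposite_eyes():
    pr, pl = synthgen.binocular_params("normal", "normal", 11)
    scene = synthgen.generate_binocular(pr, pl)
    boxes = segmentation.detect_eyes(segmentation.segment(scene.image))
    assert sorted(b.laterality for b in boxes) == ["left", "right"]


def test_overlapping_eyes_rejected():
    pr = params_for_condition("normal", 1, laterality="right")
    pl = params_for_condition("normal", 2, laterality="left")
    with pytest.raises(SceneValidationError, match="disjoint"):
        synthgen.generate_binocular(pr, pl)
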