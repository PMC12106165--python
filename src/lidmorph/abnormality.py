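"""Region-level abnormality detection.

Three detector families feed the atlas:

* parametric screening of the morphometry report against configurable
  millimetre thresholds (ptosis, upper/lower lid retraction);
* pluggable region classifiers for the inner-canthus and eyelid patches, with
  deterministic texture baselines for synthetic scenes;
* a tumor segmentator with a lesion-area threshold, reporting the calibrated
  area for surgical planning.

Every finding carries a (region, change) pair from the exported admissibility
table, a score in [0, 1], and an evidence payload naming the parameter,
lesion area, or classifier margin that produced it — the interpretability
surface of the whole system.

For the three parametric detectors the score is a logistic of the signed
threshold margin (slope 0.5 mm), so a finding fires exactly when the strict
millimetre inequality holds, i.e. score > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage

from .anatomy import RegionPatch
from .morphometry import MorphometryReport, ScaleFactor
from .palette import ECTROPION_COLOR, FOLD_COLOR, LASH_COLOR, TUMOR

__all__ = [
    "Thresholds",
    "Finding",
    "AbnormalityError",
    "ADMISSIBLE",
    "CHANGES",
    "detect_parametric",
    "parametric_scores",
    "classify_inner_canthus",
    "classify_eyelid",
    "segment_tumor",
    "RegionClassifier",
    "BaselineInnerCanthusClassifier",
    "BaselineEyelidClassifier",
]

CHANGES = (
    "entropion_trichiasis",
    "lower_retraction",
    "upper_retraction",
    "ectropion",
    "tumor",
    "ptosis",
    "epicanthus_inversus",
    "epicanthus_other",
)

#: Which changes may be reported in which anatomical region.  Tumors are
#: region-agnostic.
ADMISSIBLE: dict[str, frozenset[str]] = {
    "upper_eyelid": frozenset({"ptosis", "upper_retraction", "entropion_trichiasis", "tumor"}),
    "lower_eyelid": frozenset({"lower_retraction", "ectropion", "entropion_trichiasis", "tumor"}),
    "inner_canthus": frozenset({"epicanthus_inversus", "epicanthus_other", "tumor"}),
    "outer_canthus": frozenset({"tumor"}),
}

_LOGISTIC_SLOPE_MM = 0.5


class AbnormalityError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Millimetre screening thresholds (config, clinical-convention defaults)."""

    ptosis_mrd1_max_mm: float = 2.0
    upper_retraction_mrd1_min_mm: float = 5.0
    lower_retraction_mrd2_min_mm: float = 5.5
    tumor_min_area_mm2: float = 1.0
    bpes_icd_max_mm: float = 30.0

    def __post_init__(self) -> None:
        vals = [
            self.ptosis_mrd1_max_mm,
            self.upper_retraction_mrd1_min_mm,
            self.lower_retraction_mrd2_min_mm,
            self.tumor_min_area_mm2,
            self.bpes_icd_max_mm,
        ]
        if any(v <= 0 for v in vals):
            raise AbnormalityError("thresholds must be positive")
        if self.ptosis_mrd1_max_mm >= self.upper_retraction_mrd1_min_mm:
            raise AbnormalityError("ptosis threshold must lie below the retraction threshold")

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        return cls(**d)


@dataclass(frozen=True)
class Finding:
    region: str
    change: str
    score: float
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in ADMISSIBLE:
            raise AbnormalityError(f"unknown region {self.region!r}")
        if self.change not in ADMISSIBLE[self.region]:
            raise AbnormalityError(
                f"change {self.change!r} not admissible in region {self.region!r}"
            )
        if not 0.0 <= self.score <= 1.0:
            raise AbnormalityError("score must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "change": self.change,
            "score": float(self.score),
            "evidence": dict(self.evidence),
        }


def _logistic(margin_mm: float) -> float:
    return float(1.0 / (1.0 + np.exp(-margin_mm / _LOGISTIC_SLOPE_MM)))


def parametric_scores(report: MorphometryReport, th: Thresholds) -> dict[str, float]:
    """Logistic scores for the three MRD screens; 0.5 exactly at threshold."""
    return {
        "ptosis": _logistic(th.ptosis_mrd1_max_mm - report.mrd1_mm),
        "upper_retraction": _logistic(report.mrd1_mm - th.upper_retraction_mrd1_min_mm),
        "lower_retraction": _logistic(report.mrd2_mm - th.lower_retraction_mrd2_min_mm),
    }


def detect_parametric(report: MorphometryReport, th: Thresholds) -> list[Finding]:
    """Threshold screening of MRD1/MRD2: a finding fires iff score > 0.5."""
    scores = parametric_scores(report, th)
    spec = [
        ("ptosis", "upper_eyelid", "mrd1_mm", report.mrd1_mm, th.ptosis_mrd1_max_mm),
        ("upper_retraction", "upper_eyelid", "mrd1_mm", report.mrd1_mm,
         th.upper_retraction_mrd1_min_mm),
        ("lower_retraction", "lower_eyelid", "mrd2_mm", report.mrd2_mm,
         th.lower_retraction_mrd2_min_mm),
    ]
    findings = []
    for change, region, param, value, threshold in spec:
        score = scores[change]
        if score > 0.5:
            findings.append(
                Finding(
                    region=region,
                    change=change,
                    score=score,
                    evidence={"parameter": param, "value": float(value),
                              "threshold_mm": float(threshold)},
                )
            )
    return findings


class RegionClassifier(Protocol):
    """Pluggable classifier contract: patch in, (label, probability) out."""

    def __call__(self, patch: RegionPatch) -> tuple[str, float]: ...


def _texture_pixels(image: np.ndarray, color: tuple[int, int, int], tol: float = 30.0) -> int:
    img = np.asarray(image)
    if img.ndim == 2:
        return 0
    d2 = ((img[..., :3].astype(np.int32) - np.asarray(color, np.int32)) ** 2).sum(axis=-1)
    return int((d2 <= tol * tol).sum())


def _texture_coords(image: np.ndarray, color: tuple[int, int, int], tol: float = 30.0):
    img = np.asarray(image)
    d2 = ((img[..., :3].astype(np.int32) - np.asarray(color, np.int32)) ** 2).sum(axis=-1)
    return np.nonzero(d2 <= tol * tol)


@dataclass
class BaselineInnerCanthusClassifier:
    """Fold-texture baseline for the inner-canthus patch.

    Decides fold presence from the fraction of the patch covered by the fold
    shade, and the fold type from its vertical placement relative to the patch
    centre: a band arising from below (epicanthus inversus, lower-lid origin)
    sits under the canthus, other epicanthal folds above it.
    """

    min_coverage: float = 0.01

    def __call__(self, patch: RegionPatch) -> tuple[str, float]:
        h, w = patch.image.shape[:2]
        ys, _xs = _texture_coords(patch.image, FOLD_COLOR)
        frac = len(ys) / max(1, h * w)
        prob = float(1.0 / (1.0 + np.exp(-(frac - self.min_coverage) / (self.min_coverage / 4))))
        if prob <= 0.5:
            return ("none", 1.0 - prob)
        label = "epicanthus_inversus" if ys.mean() > (h - 1) / 2 else "epicanthus_other"
        return (label, prob)


@dataclass
class BaselineEyelidClassifier:
    """Margin-texture baseline for the eyelid patches (multi-label).

    Counts pixels of the inward-lash shade (entropion/trichiasis) and of the
    everted-band shade (ectropion) inside the patch image.
    """

    min_pixels: int = 25

    def scores(self, patch: RegionPatch) -> dict[str, float]:
        out = {}
        for change, color in (
            ("entropion_trichiasis", LASH_COLOR),
            ("ectropion", ECTROPION_COLOR),
        ):
            n = _texture_pixels(patch.image, color)
            out[change] = float(1.0 / (1.0 + np.exp(-(n - self.min_pixels) / 8.0)))
        return out

    def __call__(self, patch: RegionPatch) -> tuple[str, float]:
        scores = self.scores(patch)
        label, prob = max(scores.items(), key=lambda kv: kv[1])
        return (label, prob) if prob > 0.5 else ("none", 1.0 - prob)


def classify_inner_canthus(
    patch: RegionPatch, clf: RegionClassifier | None = None
) -> Finding | None:
    """Inner-canthus classification; returns None for 'none' or degenerate patches."""
    if min(patch.side) <= 4:
        return None
    clf = clf or BaselineInnerCanthusClassifier()
    label, prob = clf(patch)
    if label == "none":
        return None
    return Finding(
        region="inner_canthus",
        change=label,
        score=min(1.0, float(prob)),
        evidence={"classifier": type(clf).__name__, "probability": float(prob)},
    )


def classify_eyelid(
    patch: RegionPatch, clf: "BaselineEyelidClassifier | None" = None
) -> list[Finding]:
    """Eyelid-patch classification; multi-label, admissibility-filtered."""
    if min(patch.side) <= 4:
        return []
    clf = clf or BaselineEyelidClassifier()
    scores = clf.scores(patch) if hasattr(clf, "scores") else dict([clf(patch)])
    findings = []
    for change, prob in sorted(scores.items()):
        if prob <= 0.5 or change == "none":
            continue
        if change not in ADMISSIBLE[patch.region]:
            continue
        findings.append(
            Finding(
                region=patch.region,
                change=change,
                score=min(1.0, float(prob)),
                evidence={"classifier": type(clf).__name__, "probability": float(prob)},
            )
        )
    return findings


def segment_tumor(
    mask_labels: np.ndarray,
    scale: ScaleFactor,
    th: Thresholds,
    *,
    region_hint: str = "lower_eyelid",
) -> tuple[np.ndarray, float, Finding | None]:
    """Lesion mask and calibrated area from the tumor label raster.

    Emits a finding iff the largest-lesion area reaches the configured
    minimum; the mask and area are always returned so sub-threshold lesions
    remain visible in the report.
    """
    lesion = np.asarray(mask_labels) == TUMOR
    if not lesion.any():
        return (lesion, 0.0, None)
    comp, n = ndimage.label(lesion)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    area_mm2 = float(sizes[largest - 1]) * scale.mm_per_px**2
    finding = None
    if area_mm2 >= th.tumor_min_area_mm2:
        score = float(1.0 / (1.0 + np.exp(-(area_mm2 - th.tumor_min_area_mm2) / 0.25)))
        finding = Finding(
            region=region_hint,
            change="tumor",
            score=max(0.5, min(1.0, score)),
            evidence={"lesion_area_mm2": area_mm2,
                      "threshold_mm2": float(th.tumor_min_area_mm2)},
        )
    return (comp == largest, area_mm2, finding)
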