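"""The morphological atlas: declarative rules from findings to diagnoses.

Rules are data (YAML), not code.  Each rule names a disease, the (region,
change) findings it requires, optional millimetre predicates on the
morphometry report, a priority, and the component diseases it subsumes.
Rules fire in descending priority; when a composite rule (BPES) fires it
consumes its required findings, so its component diseases are not
co-reported.  Multimorbidity needs no enumeration of combinations: the
diagnosis is simply the union of everything that fires.

The module also carries the eye-level multi-label evaluation: per-class
accuracy / sensitivity / specificity / F1 / AUROC (one-vs-rest, the eye as
the unit), aACC as the unweighted mean of per-class accuracies, and the
per-eye confusion categories correct / over-detection / under-detection /
misdetection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from .abnormality import ADMISSIBLE, CHANGES, Finding
from .morphometry import MorphometryReport

__all__ = [
    "AtlasRule",
    "Diagnosis",
    "EvaluationReport",
    "AtlasError",
    "DISEASES",
    "apply_atlas",
    "default_rules",
    "load_rules",
    "save_rules",
    "evaluate",
]


class AtlasError(ValueError):
    pass


#: The recognizable disease labels (the atlas' output vocabulary).
DISEASES = (
    "blepharoptosis",
    "tao",
    "ectropion",
    "entropion_and_trichiasis",
    "eyelid_tumor",
    "epicanthus_inversus",
    "epicanthus_other",
    "bpes",
)


@dataclass(frozen=True)
class AtlasRule:
    disease: str
    required_changes: tuple[tuple[str | None, str], ...]  # (region or None=any, change)
    param_predicates: tuple[tuple[str, str, float], ...] = ()  # (param, op, value)
    priority: int = 0
    subsumes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.required_changes and not self.param_predicates:
            raise AtlasError(f"rule for {self.disease!r} requires no evidence at all")
        for region, change in self.required_changes:
            if change not in CHANGES:
                raise AtlasError(f"unknown change {change!r} in rule {self.disease!r}")
            if region is not None and change not in ADMISSIBLE.get(region, ()):
                raise AtlasError(
                    f"rule {self.disease!r}: change {change!r} inadmissible in {region!r}"
                )

    def to_dict(self) -> dict:
        d: dict = {
            "disease": self.disease,
            "requires": [
                {"region": region, "change": change}
                for region, change in self.required_changes
            ],
        }
        if self.param_predicates:
            d["params"] = [
                {"param": p, "op": op, "value": v} for p, op, v in self.param_predicates
            ]
        if self.priority:
            d["priority"] = self.priority
        if self.subsumes:
            d["subsumes"] = list(self.subsumes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AtlasRule":
        return cls(
            disease=d["disease"],
            required_changes=tuple(
                (r.get("region"), r["change"]) for r in d.get("requires", [])
            ),
            param_predicates=tuple(
                (p["param"], p["op"], float(p["value"])) for p in d.get("params", [])
            ),
            priority=int(d.get("priority", 0)),
            subsumes=tuple(d.get("subsumes", [])),
        )


@dataclass
class Diagnosis:
    eye_id: str
    diseases: set[str]
    evidence: dict[str, list[dict]]
    scores: dict[str, float]
    report: MorphometryReport | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "diseases": sorted(self.diseases),
            "evidence": {k: self.evidence[k] for k in sorted(self.evidence)},
            "scores": {k: float(v) for k, v in sorted(self.scores.items())},
            "notes": list(self.notes),
        }


def _check_predicate(report: MorphometryReport, param: str, op: str, value: float) -> float | None:
    actual = float(getattr(report, param))
    ok = {"lt": actual < value, "le": actual <= value,
          "gt": actual > value, "ge": actual >= value}.get(op)
    if ok is None:
        raise AtlasError(f"unknown predicate operator {op!r}")
    return actual if ok else None


def apply_atlas(
    findings: list[Finding],
    report: MorphometryReport,
    rules: list[AtlasRule],
    *,
    eye_id: str = "eye",
) -> Diagnosis:
    """Fire every satisfied rule, with composite rules consuming their findings.

    Deterministic regardless of finding order: findings are canonicalized and
    rules are processed by (priority desc, disease name).
    """
    for f in findings:
        if f.change not in CHANGES:
            raise AtlasError(
                f"unknown change label {f.change!r}; add an atlas rule for it"
            )
    pool = sorted(findings, key=lambda f: (f.region, f.change, -f.score))
    consumed: set[int] = set()
    diseases: set[str] = set()
    evidence: dict[str, list[dict]] = {}
    scores: dict[str, float] = {}
    notes: list[str] = []

    def match(rule: AtlasRule, available_only: bool) -> list[int] | None:
        picked: list[int] = []
        for region, change in rule.required_changes:
            found = None
            for i, f in enumerate(pool):
                if i in picked or (available_only and i in consumed):
                    continue
                if f.change == change and (region is None or f.region == region):
                    found = i
                    break
            if found is None:
                return None
            picked.append(found)
        return picked

    for rule in sorted(rules, key=lambda r: (-r.priority, r.disease)):
        picked = match(rule, available_only=True)
        if picked is None:
            continue
        pred_evidence = []
        satisfied = True
        for param, op, value in rule.param_predicates:
            actual = _check_predicate(report, param, op, value)
            if actual is None:
                satisfied = False
                break
            pred_evidence.append(
                {"predicate": f"{param} {op} {value}", "value": actual}
            )
        if not satisfied:
            continue
        diseases.add(rule.disease)
        ev = [pool[i].to_dict() for i in picked] + pred_evidence
        evidence.setdefault(rule.disease, []).extend(ev)
        sc = [pool[i].score for i in picked]
        scores[rule.disease] = max(
            scores.get(rule.disease, 0.0), float(min(sc)) if sc else 1.0
        )
        if rule.subsumes:
            consumed.update(picked)
            notes.append(
                f"{rule.disease} subsumed component findings of {sorted(rule.subsumes)}"
            )
    return Diagnosis(
        eye_id=eye_id, diseases=diseases, evidence=evidence, scores=scores,
        report=report, notes=notes,
    )


# ---------------------------------------------------------------------------
# Rule serialization

def load_rules(source) -> list[AtlasRule]:
    """Load rules from a YAML path, file object, or already-parsed dict."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return [AtlasRule.from_dict(d) for d in doc["rules"]]


def save_rules(rules: list[AtlasRule], path, *, version: str = "1") -> None:
    doc = {"schema_version": version, "rules": [r.to_dict() for r in rules]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_rules() -> list[AtlasRule]:
    """The shipped atlas: single-disease rules plus the BPES composite."""
    text = resources.files("lidmorph").joinpath("data/atlas_rules.yaml").read_text()
    return load_rules(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Eye-level multi-label evaluation

@dataclass
class EvaluationReport:
    per_class: pd.DataFrame  # index: class; columns: acc, sensitivity, specificity, f1, auroc
    aacc: float
    exact_match_acc: float
    categories: dict[str, int]  # correct / over_detection / under_detection / misdetection
    per_class_categories: pd.DataFrame
    n_eyes: int

    def to_dict(self) -> dict:
        return {
            "aacc": float(self.aacc),
            "exact_match_acc": float(self.exact_match_acc),
            "n_eyes": int(self.n_eyes),
            "categories": dict(self.categories),
            "per_class": self.per_class.to_dict(orient="index"),
        }


def _categorize(pred: set[str], truth: set[str]) -> str:
    if pred == truth:
        return "correct"
    if pred > truth:
        return "over_detection"
    if pred < truth:
        return "under_detection"
    return "misdetection"


def evaluate(
    predictions: list,
    truth: list[set[str]],
    *,
    labels: list[str] | None = None,
) -> EvaluationReport:
    """Per-class one-vs-rest metrics with the eye as the unit of measurement.

    ``predictions`` may be Diagnosis objects or plain label sets; scores for
    AUROC come from ``Diagnosis.scores`` when available (1/0 otherwise).
    AUROC is NaN for a class with no positives or no negatives.
    """
    if len(predictions) != len(truth):
        raise AtlasError("predictions and truth must have the same length")
    pred_sets = [p.diseases if isinstance(p, Diagnosis) else set(p) for p in predictions]
    truth_sets = [set(t) for t in truth]
    if labels is None:
        labels = sorted(set().union(*pred_sets, *truth_sets)) if pred_sets else []

    rows = {}
    cat_rows = {}
    for cls in labels:
        y_true = np.array([cls in t for t in truth_sets], dtype=int)
        y_pred = np.array([cls in p for p in pred_sets], dtype=int)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        n = len(y_true)
        acc = (tp + tn) / n if n else np.nan
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
        y_score = np.array(
            [
                p.scores.get(cls, 1.0 if cls in p.diseases else 0.0)
                if isinstance(p, Diagnosis)
                else float(cls in p)
                for p in predictions
            ]
        )
        auroc = (
            float(roc_auc_score(y_true, y_score))
            if 0 < y_true.sum() < len(y_true)
            else np.nan
        )
        rows[cls] = {
            "acc": acc, "sensitivity": sens, "specificity": spec,
            "f1": f1, "auroc": auroc,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
        cls_cats = {"correct": 0, "over_detection": 0, "under_detection": 0,
                    "misdetection": 0}
        for p, t in zip(pred_sets, truth_sets):
            if cls in t:
                cls_cats[_categorize(p, t)] += 1
        cat_rows[cls] = cls_cats

    categories = {"correct": 0, "over_detection": 0, "under_detection": 0,
                  "misdetection": 0}
    for p, t in zip(pred_sets, truth_sets):
        categories[_categorize(p, t)] += 1

    per_class = pd.DataFrame.from_dict(rows, orient="index")
    exact = categories["correct"] / len(pred_sets) if pred_sets else np.nan
    return EvaluationReport(
        per_class=per_class,
        aacc=float(per_class["acc"].mean()) if len(per_class) else np.nan,
        exact_match_acc=float(exact),
        categories=categories,
        per_class_categories=pd.DataFrame.from_dict(cat_rows, orient="index"),
        n_eyes=len(pred_sets),
    )
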