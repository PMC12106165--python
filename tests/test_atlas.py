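"""Atlas rule engine and eye-level multi-label evaluation."""

import itertools

import numpy as np
import pytest

from lidmorph.abnormality import Finding
from lidmorph.atlas import (
    AtlasError,
    AtlasRule,
    Diagnosis,
    apply_atlas,
    default_rules,
    evaluate,
    load_rules,
    save_rules,
)
from lidmorph.morphometry import MorphometryReport


def _report(icd_mm: float = 28.0) -> MorphometryReport:
    return MorphometryReport(
        mrd1_mm=3.5, mrd2_mm=3.5, pf_mm=7.0,
        corneal_area_mm2=70.0, lateral_area_mm2=30.0, medial_area_mm2=30.0,
        upper_lid_length_mm=30.0, lower_lid_length_mm=30.0,
        corneal_center_px=(100.0, 100.0), axis_column=100, icd_mm=icd_mm,
    )


F = {
    "ptosis": Finding("upper_eyelid", "ptosis", 0.9),
    "inversus": Finding("inner_canthus", "epicanthus_inversus", 0.9),
    "other": Finding("inner_canthus", "epicanthus_other", 0.9),
    "ectropion": Finding("lower_eyelid", "ectropion", 0.9),
    "ent_tri": Finding("upper_eyelid", "entropion_trichiasis", 0.9),
    "up_ret": Finding("upper_eyelid", "upper_retraction", 0.9),
    "lo_ret": Finding("lower_eyelid", "lower_retraction", 0.9),
    "tumor": Finding("lower_eyelid", "tumor", 0.9),
}


class TestRuleEngine:
    @pytest.mark.parametrize("keys,expected", [
        (["ptosis"], {"blepharoptosis"}),
        (["up_ret"], {"tao"}),
        (["lo_ret"], {"tao"}),
        (["ectropion"], {"ectropion"}),
        (["ent_tri"], {"entropion_and_trichiasis"}),
        (["tumor"], {"eyelid_tumor"}),
        (["inversus"], {"epicanthus_inversus"}),
        (["other"], {"epicanthus_other"}),
        ([], set()),
        (["ptosis", "ectropion"], {"blepharoptosis", "ectropion"}),
        (["ptosis", "other"], {"blepharoptosis", "epicanthus_other"}),
        (["ptosis", "ent_tri"], {"blepharoptosis", "entropion_and_trichiasis"}),
    ])
    def test_default_rules_single_and_multimorbid(self, keys, expected):
        d = apply_atlas([F[k] for k in keys], _report(), default_rules())
        assert d.diseases == expected

    def test_bpes_subsumes_components_when_icd_short(self):
        findings = [F["ptosis"], F["inversus"]]
        d = apply_atlas(findings, _report(icd_mm=22.0), default_rules())
        assert d.diseases == {"bpes"}
        assert any("subsumed" in note for note in d.notes)
        # every disease cites evidence
        assert d.evidence["bpes"]

    def test_bpes_requires_short_icd(self):
        d = apply_atlas([F["ptosis"], F["inversus"]], _report(icd_mm=31.0),
                        default_rules())
        assert d.diseases == {"blepharoptosis", "epicanthus_inversus"}

    def test_diagnosis_invariant_every_disease_justified(self):
        d = apply_atlas([F["ptosis"], F["tumor"]], _report(), default_rules())
        for disease in d.diseases:
            assert len(d.evidence[disease]) >= 1

    def test_order_invariance(self):
        findings = [F["ptosis"], F["inversus"], F["ectropion"]]
        results = {
            frozenset(apply_atlas(list(perm), _report(22.0), default_rules()).diseases)
            for perm in itertools.permutations(findings)
        }
        assert len(results) == 1

    def test_monotonicity_except_logged_subsumption(self):
        rules = default_rules()
        base = apply_atlas([F["ptosis"]], _report(22.0), rules)
        grown = apply_atlas([F["ptosis"], F["ectropion"]], _report(22.0), rules)
        assert base.diseases <= grown.diseases
        # the one exception: the BPES composite, and it is logged
        subsumed = apply_atlas([F["ptosis"], F["inversus"]], _report(22.0), rules)
        assert "blepharoptosis" not in subsumed.diseases
        assert subsumed.notes

    def test_unknown_change_label_named_in_error(self):
        bad = Finding.__new__(Finding)
        object.__setattr__(bad, "region", "upper_eyelid")
        object.__setattr__(bad, "change", "madarosis")
        object.__setattr__(bad, "score", 0.9)
        object.__setattr__(bad, "evidence", {})
        with pytest.raises(AtlasError, match="madarosis"):
            apply_atlas([bad], _report(), default_rules())

    def test_rules_are_data_round_trip(self, tmp_path):
        rules = default_rules()
        path = tmp_path / "rules.yaml"
        save_rules(rules, path)
        reloaded = load_rules(path)
        fixture_sets = [["ptosis"], ["ptosis", "inversus"], ["tumor", "ectropion"], []]
        for keys in fixture_sets:
            a = apply_atlas([F[k] for k in keys], _report(22.0), rules).diseases
            b = apply_atlas([F[k] for k in keys], _report(22.0), reloaded).diseases
            assert a == b

    def test_rule_validation(self):
        with pytest.raises(AtlasError, match="no evidence"):
            AtlasRule(disease="x", required_changes=())
        with pytest.raises(AtlasError, match="inadmissible"):
            AtlasRule(disease="x", required_changes=(("inner_canthus", "ptosis"),))

    def test_expandability_new_rule_not_code(self):
        # adding a disease is one data entry, no code changes
        rules = default_rules() + [
            AtlasRule(disease="lagophthalmos_screen",
                      required_changes=((None, "upper_retraction"),),
                      param_predicates=(("pf_mm", "gt", 6.5),))
        ]
        d = apply_atlas([F["up_ret"]], _report(), rules)
        assert {"tao", "lagophthalmos_screen"} == d.diseases


# ---------------------------------------------------------------------------
# Evaluation vs brute-force oracles

def _brute_confusion(preds, truths, cls):
    tp = sum(cls in p and cls in t for p, t in zip(preds, truths))
    fp = sum(cls in p and cls not in t for p, t in zip(preds, truths))
    fn = sum(cls not in p and cls in t for p, t in zip(preds, truths))
    tn = sum(cls not in p and cls not in t for p, t in zip(preds, truths))
    return tp, fp, fn, tn


def _pairwise_auroc(scores, y):
    """Mann-Whitney concordance: P(score_pos > score_neg) + ½P(tie)."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    if not pos or not neg:
        return np.nan
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluation:
    def test_perfect_predictions(self):
        truth = [{"blepharoptosis"}, set(), {"tao"}, {"tao", "ectropion"}] + [set()] * 6
        rep = evaluate(truth, truth)
        assert (rep.per_class["acc"] == 1.0).all()
        assert rep.aacc == 1.0
        assert rep.exact_match_acc == 1.0
        assert rep.categories["correct"] == 10

    def test_toy_metrics_equal_bruteforce_confusion(self):
        # 8 eyes, 2 classes; class A has 1 FP and 1 FN
        truth = [{"A"}, {"A"}, {"A"}, set(), set(), {"B"}, {"B"}, set()]
        pred = [{"A"}, {"A"}, set(), {"A"}, set(), {"B"}, {"B"}, set()]
        rep = evaluate(pred, truth, labels=["A", "B"])
        for cls in ("A", "B"):
            tp, fp, fn, tn = _brute_confusion(pred, truth, cls)
            row = rep.per_class.loc[cls]
            assert row["acc"] == pytest.approx((tp + tn) / 8)
            assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert row["specificity"] == pytest.approx(tn / (tn + fp))
            assert row["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
        assert rep.aacc == pytest.approx(
            (rep.per_class.loc["A", "acc"] + rep.per_class.loc["B", "acc"]) / 2
        )

    def test_confusion_categories_per_eye(self):
        truth = [{"A"}, {"A", "B"}, {"A"}, {"A"}]
        pred = [{"A"}, {"A"}, {"A", "B"}, {"B"}]
        rep = evaluate(pred, truth, labels=["A", "B"])
        assert rep.categories == {
            "correct": 1, "under_detection": 1, "over_detection": 1,
            "misdetection": 1,
        }

    def test_auroc_equals_pairwise_concordance(self):
        truth = [{"A"}, {"A"}, {"A"}, set(), set(), set(), {"A"}, set()]
        scores = [0.9, 0.8, 0.55, 0.6, 0.2, 0.1, 0.4, 0.4]
        preds = [
            Diagnosis(eye_id=str(i), diseases={"A"} if s > 0.5 else set(),
                      evidence={}, scores={"A": s})
            for i, s in enumerate(scores)
        ]
        rep = evaluate(preds, truth, labels=["A"])
        y = [1 if "A" in t else 0 for t in truth]
        assert rep.per_class.loc["A", "auroc"] == pytest.approx(
            _pairwise_auroc(scores, y)
        )

    def test_degenerate_class_auroc_is_nan(self):
        rep = evaluate([set(), set()], [set(), set()], labels=["A"])
        assert np.isnan(rep.per_class.loc["A", "auroc"])
        assert np.isnan(rep.per_class.loc["A", "sensitivity"])

    def test_mismatched_lengths_raise(self):
        with pytest.raises(AtlasError, match="same length"):
            evaluate([set()], [set(), set()])
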