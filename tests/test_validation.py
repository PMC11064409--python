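import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pheindex.criteria import CRITERIA
from pheindex.validation import (
    ConfusionSummary,
    ValidationError,
    adjusted_ppv,
    confusion,
    per_criterion_accuracy,
    sample_chart_review,
)


def build_review(tp, fp, tn, fn, unknown_pos=0, unknown_neg=0):
    """Construct aligned prediction/gold series with the given cell counts."""
    preds = (
        [True] * (tp + fp + unknown_pos) + [False] * (fn + tn + unknown_neg)
    )
    golds = (
        ["has_disease"] * tp
        + ["no_disease"] * fp
        + ["unknown"] * unknown_pos
        + ["has_disease"] * fn
        + ["no_disease"] * tn
        + ["unknown"] * unknown_neg
    )
    idx = [f"C{i}" for i in range(len(preds))]
    return pd.Series(preds, index=idx), pd.Series(golds, index=idx)


class TestConfusion:
    def test_unknowns_excluded_before_counting(self):
        pred, gold = build_review(tp=85, fp=3, tn=91, fn=9, unknown_pos=12)
        s = confusion(pred, gold)
        assert (s.tp, s.fp, s.tn, s.fn) == (85, 3, 91, 9)
        assert s.n_excluded_unknown == 12
        assert s.n_evaluated == 188

    def test_perfect_agreement_all_hundred(self):
        pred, gold = build_review(tp=10, fp=0, tn=10, fn=0)
        assert all(v == 100 for v in confusion(pred, gold).rounded().values())

    def test_zero_denominator_flagged_not_crashed(self):
        s = ConfusionSummary(tp=1, fp=0, tn=0, fn=1)
        assert s.sensitivity == pytest.approx(50.0)
        assert s.specificity is None
        assert "specificity" in s.undefined_metrics
        assert s.rounded()["specificity"] is None

    def test_missing_prediction_rejected(self):
        pred = pd.Series([True], index=["C0"])
        gold = pd.Series(["has_disease", "no_disease"], index=["C0", "C1"])
        with pytest.raises(ValidationError):
            confusion(pred, gold)

    def test_all_unknown_rejected(self):
        pred = pd.Series([True], index=["C0"])
        gold = pd.Series(["unknown"], index=["C0"])
        with pytest.raises(ValidationError):
            confusion(pred, gold)

    def test_string_predictions_accepted(self):
        pred = pd.Series(["positive", "negative"], index=["C0", "C1"])
        gold = pd.Series(["has_disease", "no_disease"], index=["C0", "C1"])
        assert confusion(pred, gold).accuracy == pytest.approx(100.0)

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50), st.integers(2, 5))
    @settings(max_examples=50, deadline=None)
    def test_metrics_scale_invariant(self, tp, fp, tn, fn, k):
        a = ConfusionSummary(tp, fp, tn, fn)
        b = ConfusionSummary(tp * k, fp * k, tn * k, fn * k)
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            va, vb = getattr(a, m), getattr(b, m)
            if va is None:
                assert vb is None
            else:
                assert va == pytest.approx(vb)


class TestAdjustedPpv:
    def test_limit_prevalence_one(self):
        assert adjusted_ppv(0.9, 0.97, 1.0) == pytest.approx(1.0)

    def test_perfect_specificity_gives_one(self):
        assert adjusted_ppv(0.9, 1.0, 0.03) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjusted_ppv(0.0, 0.9, 0.03)

    def test_monotone_in_prevalence_and_specificity(self):
        prevs = np.linspace(0.01, 0.99, 25)
        vals = [adjusted_ppv(0.9, 0.97, p) for p in prevs]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        specs_grid = np.linspace(0.5, 0.999, 25)
        vals = [adjusted_ppv(0.9, s, 0.03) for s in specs_grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


def profiles_with_disagreements(n, disagreements):
    """Gold all-False profiles and predictions flipping `disagreements[c]`
    children per criterion."""
    idx = [f"C{i}" for i in range(n)]
    gold = pd.DataFrame(False, index=idx, columns=list(CRITERIA))
    pred = gold.copy()
    for c, k in disagreements.items():
        pred.iloc[:k, list(CRITERIA).index(c)] = True
    return pred, gold


class TestPerCriterionAccuracy:
    def test_identical_profiles_all_hundred(self):
        pred, gold = profiles_with_disagreements(50, {})
        out = per_criterion_accuracy(pred, gold)
        assert (out["accuracy_pct"] == 100.0).all()

    def test_known_disagreement_rate(self):
        # 38 NICU disagreements among 200 children -> 81%
        pred, gold = profiles_with_disagreements(200, {"nicu_stay": 38})
        out = per_criterion_accuracy(pred, gold).set_index("criterion")
        assert out.loc["nicu_stay", "accuracy_pct"] == pytest.approx(81.0)

    def test_mismatched_children_rejected(self):
        pred, gold = profiles_with_disagreements(10, {})
        with pytest.raises(ValidationError):
            per_criterion_accuracy(pred.iloc[:5], gold)


def results_frame(scores_pos, scores_neg):
    rows = []
    for i, s in enumerate(scores_pos):
        rows.append({"child_id": f"P{i}", "score": s, "classification": "positive"})
    for i, s in enumerate(scores_neg):
        rows.append({"child_id": f"N{i}", "score": s, "classification": "negative"})
    return pd.DataFrame(rows)


class TestChartReviewSampler:
    def test_reproducible_and_right_sizes(self):
        rng = np.random.default_rng(1)
        res = results_frame(rng.integers(3, 22, 300), rng.integers(0, 7, 5000))
        a = sample_chart_review(res, 100, 100, seed=7)
        b = sample_chart_review(res, 100, 100, seed=7)
        assert list(a["child_id"]) == list(b["child_id"])
        assert (a["classification"] == "positive").sum() == 100
        assert (a["classification"] == "negative").sum() == 100
        assert not a["child_id"].duplicated().any()

    def test_covers_score_range(self):
        rng = np.random.default_rng(2)
        res = results_frame(rng.integers(3, 22, 500), rng.integers(0, 7, 5000))
        s = sample_chart_review(res, 100, 100, seed=3)
        pos = s[s["classification"] == "positive"]["score"]
        neg = s[s["classification"] == "negative"]["score"]
        assert pos.min() == 3 and pos.max() == 21
        assert neg.min() == 0 and neg.max() == 6

    def test_insufficient_stratum_errors(self):
        res = results_frame([5] * 10, [0] * 10)
        with pytest.raises(ValidationError, match="positive"):
            sample_chart_review(res, 100, 5, seed=0)

    def test_degenerate_single_score_stratum(self):
        res = results_frame([5] * 150, [0] * 150)
        s = sample_chart_review(res, 100, 100, seed=0)
        assert len(s) == 200
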