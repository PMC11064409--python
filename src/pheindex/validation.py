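"""Diagnostic-validation computations against a chart-review gold standard.

The gold standard labels each reviewed child ``has_disease``,
``no_disease`` or ``unknown`` (insufficient information); unknowns are
excluded before any confusion counting.  Reported metrics are rounded to
the nearest integer percent for presentation; exact fractions are always
retained on the summary object.

``adjusted_ppv`` re-computes the positive predictive value at an assumed
population prevalence via Bayes' rule, since a case-control style
validation sample (equal numbers of positives and negatives) does not
reflect the population case mix:

    PPV(p) = sens * p / (sens * p + (1 - spec) * (1 - p))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CRITERIA

__all__ = [
    "GOLD_STATUSES",
    "ConfusionSummary",
    "ValidationError",
    "confusion",
    "adjusted_ppv",
    "per_criterion_accuracy",
    "sample_chart_review",
]

GOLD_STATUSES = ("has_disease", "no_disease", "unknown")


class ValidationError(ValueError):
    pass


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return 100.0 * num / den


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts plus derived metrics (exact percentages; use
    :meth:`rounded` for integer-percent presentation).  Metrics with a zero
    denominator are ``None`` and listed in ``undefined_metrics``."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_unknown: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return _pct(self.tp + self.tn, self.n_evaluated)

    @property
    def undefined_metrics(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
            if getattr(self, name) is None
        )

    def rounded(self) -> dict[str, int | None]:
        """Metrics rounded to the nearest integer percent."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else int(round(v))
        return out


def _as_bool_pred(pred: pd.Series) -> pd.Series:
    if pred.dtype == bool:
        return pred
    return pred.map(
        {"positive": True, "negative": False, True: True, False: False, 1: True, 0: False}
    ).astype(bool)


def confusion(pred: pd.Series, gold: pd.Series) -> ConfusionSummary:
    """Confusion summary of predicted classifications against gold labels.

    ``pred`` and ``gold`` are aligned by index (child id).  Every gold child
    must have a prediction; ``unknown`` gold labels are excluded before
    counting.  Raises if the evaluable set is empty.
    """
    bad = set(gold.unique()) - set(GOLD_STATUSES)
    if bad:
        raise ValidationError(f"unknown gold labels: {sorted(bad)}")
    missing = gold.index.difference(pred.index)
    if len(missing):
        raise ValidationError(f"no prediction for reviewed child {missing[0]!r}")
    keep = gold[gold != "unknown"]
    if keep.empty:
        raise ValidationError("no evaluable children after excluding unknowns")
    p = _as_bool_pred(pred.loc[keep.index])
    truth = keep == "has_disease"
    return ConfusionSummary(
        tp=int((p & truth).sum()),
        fp=int((p & ~truth).sum()),
        tn=int((~p & ~truth).sum()),
        fn=int((~p & truth).sum()),
        n_excluded_unknown=int((gold == "unknown").sum()),
    )


def adjusted_ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Prevalence-adjusted PPV via Bayes' rule (arguments as fractions)."""
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 < v <= 1.0:
            raise ValidationError(f"{name} must be in (0, 1], got {v}")
    fp_mass = (1.0 - specificity) * (1.0 - prevalence)
    tp_mass = sensitivity * prevalence
    if fp_mass == 0.0:
        return 1.0  # a perfectly specific test never false-alarms
    return tp_mass / (tp_mass + fp_mass)


def per_criterion_accuracy(
    pred_profiles: pd.DataFrame, gold_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-criterion agreement between extracted and gold met flags.

    Both frames are indexed by child id with one boolean column per
    criterion; the child sets must match.  Returns accuracy (percent, two
    decimals) per criterion plus a ``mean`` row across the 13 criteria.
    """
    if set(pred_profiles.index) != set(gold_profiles.index):
        raise ValidationError("prediction and gold cover different children")
    gold_profiles = gold_profiles.loc[pred_profiles.index]
    rows = []
    accs = []
    for cid in CRITERIA:
        agree = (
            pred_profiles[cid].astype(bool) == gold_profiles[cid].astype(bool)
        ).mean()
        acc = 100.0 * float(agree)
        accs.append(acc)
        rows.append({"criterion": cid, "accuracy_pct": round(acc, 2)})
    rows.append({"criterion": "mean", "accuracy_pct": round(float(np.mean(accs)), 2)})
    return pd.DataFrame(rows, columns=["criterion", "accuracy_pct"])


def _coverage_sample(
    scores: pd.Series, n: int, rng: np.random.Generator
) -> list:
    """Sample ``n`` ids spanning the score range: scores are binned into up
    to 10 quantile bins, one round-robin pick per non-empty bin, remainder
    filled uniformly at random without replacement."""
    ids = scores.index.to_numpy()
    vals = scores.to_numpy(float)
    order = np.argsort(vals, kind="stable")
    ids, vals = ids[order], vals[order]
    edges = np.quantile(vals, np.linspace(0, 1, 11))
    bin_of = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, 9)
    chosen: list = []
    pools = {b: list(rng.permutation(ids[bin_of == b])) for b in np.unique(bin_of)}
    while len(chosen) < n and any(pools.values()):
        for b in sorted(pools):
            if pools[b] and len(chosen) < n:
                chosen.append(pools[b].pop())
    return chosen


def sample_chart_review(
    results: pd.DataFrame,
    n_pos: int,
    n_neg: int,
    seed: int,
) -> pd.DataFrame:
    """Draw a stratified chart-review sample: ``n_pos`` classified-positive
    and ``n_neg`` classified-negative children, each stratum covering its
    available score range (decile-stratified, deterministic given seed).

    ``results`` is the classification result frame (needs ``child_id``,
    ``score``, ``classification``).  Returns the sampled rows.
    """
    rng = np.random.default_rng(seed)
    out_ids: list = []
    for label, want in (("positive", n_pos), ("negative", n_neg)):
        stratum = results[results["classification"] == label]
        if len(stratum) < want:
            raise ValidationError(
                f"not enough {label} children: need {want}, have {len(stratum)}"
            )
        scores = stratum.set_index("child_id")["score"]
        out_ids.extend(_coverage_sample(scores, want, rng))
    return results.set_index("child_id").loc[out_ids].reset_index()
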