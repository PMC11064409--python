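"""Cohort-level descriptive analytics over criteria profiles.

All functions take the tabulated profile frame produced by
:func:`pheindex.criteria.evaluate_cohort` (and, where noted, the result
frame from :func:`pheindex.scoring.classify_cohort`).  Outputs are tidy
pandas tables; plotting is deliberately left to the caller — every figure
is regenerable from these tables alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CRITERIA
from .emr import TermStatus

__all__ = [
    "JaccardMatrix",
    "criterion_frequencies",
    "jaccard_matrix",
    "time_to_criterion_curves",
    "count_and_score_distributions",
]


def criterion_frequencies(profiles: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of children meeting each criterion."""
    n = len(profiles)
    rows = []
    for cid in CRITERIA:
        cnt = int(profiles[cid].sum()) if n else 0
        rows.append(
            {
                "criterion": cid,
                "n": cnt,
                "pct": round(100.0 * cnt / n, 2) if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["criterion", "n", "pct"])


@dataclass(frozen=True)
class JaccardMatrix:
    """Term-stratified criterion co-occurrence (Jaccard) matrix.

    The pre-term stratum carries 12 labels — the NICU criterion is not
    defined there.  Pairs whose union of met children is empty are NaN
    (undefined), never 0.
    """

    stratum: TermStatus
    labels: tuple[str, ...]
    values: pd.DataFrame

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values.loc[i, j])


def jaccard_matrix(profiles: pd.DataFrame, stratum: TermStatus) -> JaccardMatrix:
    """Jaccard index J(i,j) = |met_i & met_j| / |met_i | met_j| between all
    criterion pairs, within one term stratum."""
    sub = profiles[profiles["term_status"] == stratum.value]
    labels = tuple(c for c in CRITERIA if not (stratum is TermStatus.PRE_TERM and c == "nicu_stay"))
    M = sub[list(labels)].to_numpy(dtype=bool) if len(sub) else np.zeros((0, len(labels)), bool)
    inter = (M[:, :, None] & M[:, None, :]).sum(axis=0).astype(float)
    union = (M[:, :, None] | M[:, None, :]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), np.nan)
    values = pd.DataFrame(J, index=list(labels), columns=list(labels))
    return JaccardMatrix(stratum=stratum, labels=labels, values=values)


def time_to_criterion_curves(
    profiles: pd.DataFrame, grid: np.ndarray | list[float]
) -> pd.DataFrame:
    """Cumulative fraction of met children whose first-met age is <= t,
    per criterion, normalized among the children who met the criterion
    within the window.  Criteria met by no child are omitted.

    Returns a frame indexed by the grid (days) with one column per
    criterion that has at least one met child.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) and np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    out = {}
    for cid in CRITERIA:
        ages = profiles.loc[profiles[cid].astype(bool), f"first_met_{cid}"].to_numpy(float)
        ages = ages[~np.isnan(ages)]
        if ages.size == 0:
            continue
        out[cid] = np.searchsorted(np.sort(ages), grid, side="right") / ages.size
    return pd.DataFrame(out, index=pd.Index(grid, name="age_days"))


def count_and_score_distributions(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histograms of the criteria count and of the severity score, split by
    classification.  Each table conserves the cohort size and reports
    percentages to two decimals.
    """
    n = len(results)
    met_count = results[list(CRITERIA)].astype(bool).sum(axis=1) if n else pd.Series(dtype=int)

    def _hist(values: pd.Series, name: str) -> pd.DataFrame:
        rows = []
        for v in sorted(values.unique()):
            mask = values == v
            pos = int((results.loc[mask, "classification"] == "positive").sum())
            cnt = int(mask.sum())
            rows.append(
                {
                    name: int(v),
                    "n": cnt,
                    "pct": round(100.0 * cnt / n, 2),
                    "n_positive": pos,
                    "n_negative": cnt - pos,
                }
            )
        return pd.DataFrame(rows, columns=[name, "n", "pct", "n_positive", "n_negative"])

    if not n:
        empty_c = pd.DataFrame(columns=["criteria_count", "n", "pct", "n_positive", "n_negative"])
        empty_s = pd.DataFrame(columns=["score", "n", "pct", "n_positive", "n_negative"])
        return empty_c, empty_s
    return _hist(met_count, "criteria_count"), _hist(results["score"], "score")
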