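"""Severity score and binary classification over a criteria profile.

The score is the sum of the per-criterion scores over met criteria
(maximum 25 for full-term children, 22 pre-term with the default config).
The classification is positive when any of four conditions holds:

    (a) >= 2 major criteria met,
    (b) >= 1 major and >= 1 minor criterion met,
    (c) >= 5 minor criteria met,
    (d) the child is deceased.

The a-b-c-d precedence is reporting-only (the first condition that holds
is recorded as the trigger); it never changes the binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .criteria import (
    CRITERIA,
    CriteriaProfile,
    CriterionSpec,
    default_specs,
)

__all__ = [
    "PheResult",
    "compute_score",
    "classify",
    "classify_cohort",
    "classify_matrix",
    "RESULT_COLUMNS",
]

TRIGGER_ORDER = ("a_two_major", "b_major_plus_minor", "c_five_minor", "d_deceased")

RESULT_COLUMNS = [
    "child_id",
    "term_status",
    "score",
    "n_major",
    "n_minor",
    "classification",
    "triggering_condition",
]


@dataclass(frozen=True)
class PheResult:
    child_id: str
    score: int
    n_major: int
    n_minor: int
    classification: str  # "positive" | "negative"
    triggering_condition: str | None = None

    def __post_init__(self) -> None:
        if (self.classification == "positive") != (self.triggering_condition is not None):
            raise ValueError("triggering_condition present iff positive")


def compute_score(
    profile: CriteriaProfile, specs: Mapping[str, CriterionSpec] | None = None
) -> int:
    """Sum of per-criterion scores over met criteria."""
    specs = specs or default_specs()
    return sum(specs[cid].score for cid in profile.met_ids())


def _classify_counts(n_major: int, n_minor: int, deceased: bool) -> str | None:
    if n_major >= 2:
        return "a_two_major"
    if n_major >= 1 and n_minor >= 1:
        return "b_major_plus_minor"
    if n_minor >= 5:
        return "c_five_minor"
    if deceased:
        return "d_deceased"
    return None


def classify(
    profile: CriteriaProfile, specs: Mapping[str, CriterionSpec] | None = None
) -> PheResult:
    """Score and classify one child's criteria profile."""
    specs = specs or default_specs()
    met = profile.met_ids()
    n_major = sum(1 for cid in met if specs[cid].tier == "major")
    n_minor = sum(1 for cid in met if specs[cid].tier == "minor")
    trigger = _classify_counts(n_major, n_minor, "death" in met)
    return PheResult(
        child_id=profile.child_id,
        score=compute_score(profile, specs),
        n_major=n_major,
        n_minor=n_minor,
        classification="positive" if trigger else "negative",
        triggering_condition=trigger,
    )


def classify_matrix(
    met: np.ndarray | pd.DataFrame,
    specs: Mapping[str, CriterionSpec] | None = None,
    criteria: Sequence[str] = CRITERIA,
) -> pd.DataFrame:
    """Vectorized scoring/classification of an (n, 13) boolean met matrix.

    Columns of ``met`` follow ``criteria`` order.  Returns a frame with
    score, n_major, n_minor, classification and triggering_condition.
    """
    specs = specs or default_specs()
    if isinstance(met, pd.DataFrame):
        M = met[list(criteria)].to_numpy(dtype=bool)
        index = met.index
    else:
        M = np.asarray(met, dtype=bool)
        index = pd.RangeIndex(len(M))
    if M.ndim != 2 or M.shape[1] != len(criteria):
        raise ValueError(f"met matrix must have {len(criteria)} columns")
    scores = np.array([specs[c].score for c in criteria])
    major = np.array([specs[c].tier == "major" for c in criteria])
    death_col = list(criteria).index("death")
    score = M @ scores
    n_major = M[:, major].sum(axis=1)
    n_minor = M[:, ~major].sum(axis=1)
    deceased = M[:, death_col]
    a = n_major >= 2
    b = (n_major >= 1) & (n_minor >= 1)
    c = n_minor >= 5
    d = deceased
    positive = a | b | c | d
    trigger = np.full(len(M), None, dtype=object)
    trigger[d] = "d_deceased"
    trigger[c] = "c_five_minor"
    trigger[b] = "b_major_plus_minor"
    trigger[a] = "a_two_major"
    return pd.DataFrame(
        {
            "score": score.astype(int),
            "n_major": n_major.astype(int),
            "n_minor": n_minor.astype(int),
            "classification": np.where(positive, "positive", "negative"),
            "triggering_condition": trigger,
        },
        index=index,
    )


def classify_cohort(
    profiles: pd.DataFrame, specs: Mapping[str, CriterionSpec] | None = None
) -> pd.DataFrame:
    """Classify a tabulated profile frame (as produced by
    :func:`pheindex.criteria.evaluate_cohort`).

    Returns one row per child: identifiers, term status, score, major and
    minor counts, classification, triggering condition, plus the 13 met
    flags.
    """
    specs = specs or default_specs()
    if not len(profiles):
        return pd.DataFrame(columns=RESULT_COLUMNS + list(CRITERIA))
    out = classify_matrix(profiles[list(CRITERIA)], specs)
    result = pd.concat(
        [profiles[["child_id", "term_status"]].reset_index(drop=True), out.reset_index(drop=True)],
        axis=1,
    )
    result = pd.concat([result, profiles[list(CRITERIA)].reset_index(drop=True)], axis=1)
    return result
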