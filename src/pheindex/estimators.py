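"""scikit-learn style estimators wrapping the phenotyping pipeline.

Two pieces compose into a standard sklearn :class:`~sklearn.pipeline.Pipeline`:

``CriteriaExtractor``
    A transformer taking a :class:`~pheindex.emr.Cohort` and producing the
    (n_children, 13) boolean criteria matrix (plus first-met ages, kept on
    the fitted instance).

``PheIndexClassifier``
    A deterministic rule-based classifier over the criteria matrix.  It has
    no trainable parameters — ``fit`` validates inputs and resolves the
    criterion configuration — but exposes the full estimator API
    (``fit`` / ``predict`` / ``decision_function`` / ``get_params``) so the
    rule engine drops into sklearn model selection and pipelines.
    ``decision_function`` returns the severity score.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .criteria import CRITERIA, CriterionSpec, default_specs, evaluate_cohort
from .emr import Cohort
from .scoring import classify_matrix
from .vocabulary import Vocabulary, default_vocabulary

__all__ = ["CriteriaExtractor", "PheIndexClassifier"]


class CriteriaExtractor(BaseEstimator, TransformerMixin):
    """Transform a cohort into its boolean criteria matrix.

    Parameters
    ----------
    specs : mapping of criterion id to CriterionSpec, optional
        Criterion thresholds/tiers/scores; package defaults when omitted.
    vocabulary : Vocabulary, optional
        Code sets, keyword rules and the specialty taxonomy.
    """

    def __init__(
        self,
        specs: Mapping[str, CriterionSpec] | None = None,
        vocabulary: Vocabulary | None = None,
    ):
        self.specs = specs
        self.vocabulary = vocabulary

    def fit(self, X: Cohort, y=None) -> "CriteriaExtractor":
        if not isinstance(X, Cohort):
            raise TypeError("CriteriaExtractor expects a Cohort")
        self.specs_ = self.specs or default_specs()
        self.vocabulary_ = self.vocabulary or default_vocabulary()
        self.feature_names_ = list(CRITERIA)
        return self

    def transform(self, X: Cohort) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            raise RuntimeError("CriteriaExtractor is not fitted")
        profiles = evaluate_cohort(X, self.specs_, self.vocabulary_)
        self.profiles_ = profiles
        met = profiles.set_index("child_id")[list(CRITERIA)].astype(bool)
        return met

    def get_feature_names_out(self, input_features=None):
        return np.asarray(CRITERIA, dtype=object)


class PheIndexClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier over the 13-criterion boolean matrix.

    ``predict`` returns 1 (positive: presenting with illness at increased
    risk for a rare genetic disorder) or 0.  ``decision_function`` returns
    the integer severity score.  ``y`` is ignored in ``fit``: the rules are
    fixed by the criterion configuration, not learned.
    """

    def __init__(self, specs: Mapping[str, CriterionSpec] | None = None):
        self.specs = specs

    def _validate(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = set(CRITERIA) - set(X.columns)
            if missing:
                raise ValueError(f"criteria matrix missing columns {sorted(missing)}")
            return X[list(CRITERIA)].astype(bool)
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(CRITERIA):
            raise ValueError(f"expected (n, {len(CRITERIA)}) criteria matrix")
        return pd.DataFrame(X.astype(bool), columns=list(CRITERIA))

    def fit(self, X, y=None) -> "PheIndexClassifier":
        self._validate(X)
        self.specs_ = self.specs or default_specs()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(CRITERIA)
        return self

    def predict(self, X) -> np.ndarray:
        out = self.result_frame(X)
        return (out["classification"] == "positive").to_numpy(dtype=int)

    def decision_function(self, X) -> np.ndarray:
        return self.result_frame(X)["score"].to_numpy()

    def result_frame(self, X) -> pd.DataFrame:
        """Full per-child output: score, major/minor counts, classification
        and triggering condition."""
        if not hasattr(self, "specs_"):
            raise RuntimeError("PheIndexClassifier is not fitted")
        M = self._validate(X)
        return classify_matrix(M, self.specs_)
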