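"""MEWS computation and critical-illness classification.

The score of a patient is the sum of five banded subscores (systolic BP,
pulse, respiratory rate, temperature, AVPU); a patient is labelled
critically ill when the total reaches a cutoff (5 in the source study; 4 is
the conventional alternative).  Exposed both as plain functions over
:class:`~mews_triage.records.VitalSigns` and as sklearn-style estimators
(`MEWSScorer`, `MEWSClassifier`) operating on DataFrames, so the rule
composes with pipelines and model selection.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .bands import SCORED_PARAMETERS, ScoreBands, default_bands
from .records import MEWSBreakdown, VitalSigns

__all__ = [
    "score_parameter",
    "compute_mews",
    "classify_critical",
    "MEWSScorer",
    "MEWSClassifier",
    "score_frame",
]


def score_parameter(value, parameter: str, bands: Optional[ScoreBands] = None) -> int:
    """Subscore of a single measurement under the banded rule.

    Raises ``ValueError`` naming the parameter for out-of-range or
    non-finite values.
    """
    if parameter not in SCORED_PARAMETERS:
        raise KeyError(f"parameter must be one of {SCORED_PARAMETERS}, got {parameter!r}")
    bands = bands or default_bands()
    return bands.score(parameter, value)


def compute_mews(vitals: VitalSigns, bands: Optional[ScoreBands] = None) -> MEWSBreakdown:
    """Full per-parameter breakdown and total for one observation set.

    Mirrors the study's exclusion rule: a record with any missing scored
    vital cannot be scored and is rejected (``ValueError`` listing the
    missing fields) rather than imputed.
    """
    bands = bands or default_bands()
    missing = [
        name
        for name in SCORED_PARAMETERS
        if getattr(vitals, name, None) is None
    ]
    if missing:
        raise ValueError(f"incomplete vital signs, cannot compute MEWS: missing {missing}")
    subs = {name: bands.score(name, getattr(vitals, name)) for name in SCORED_PARAMETERS}
    return MEWSBreakdown(
        sub_sbp=subs["sbp"],
        sub_pulse=subs["pulse"],
        sub_rr=subs["rr"],
        sub_temp=subs["temp"],
        sub_avpu=subs["avpu"],
        total=sum(subs.values()),
    )


def classify_critical(total: int, cutoff: int = 5) -> bool:
    """True iff the MEWS total meets the critical-illness cutoff."""
    if not (1 <= cutoff <= 14):
        raise ValueError(f"cutoff must be within 1-14, got {cutoff}")
    if not (0 <= total <= 14):
        raise ValueError(f"MEWS total must be within 0-14, got {total}")
    return total >= cutoff


def score_frame(
    frame: pd.DataFrame,
    bands: Optional[ScoreBands] = None,
    cutoffs: Sequence[int] = (4, 5),
) -> pd.DataFrame:
    """Append ``mews_total`` and per-cutoff critical flags to a patient table.

    Expects columns ``sbp``, ``pulse``, ``rr``, ``temp``, ``avpu``.  Returns a
    copy; rows are scored independently and deterministically.
    """
    bands = bands or default_bands()
    out = frame.copy()
    totals = np.empty(len(frame), dtype=int)
    for i, (_, row) in enumerate(frame.iterrows()):
        vitals = VitalSigns(
            sbp=row["sbp"], pulse=row["pulse"], rr=row["rr"],
            temp=row["temp"], avpu=row["avpu"],
        )
        totals[i] = compute_mews(vitals, bands).total
    out["mews_total"] = totals
    for cutoff in cutoffs:
        out[f"mews_critical_ge{cutoff}"] = totals >= cutoff
    return out


class MEWSScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer: vital-sign columns -> MEWS totals and flags.

    Parameters
    ----------
    bands : ScoreBands, optional
        Scoring rule; the standard gap-closed rule when omitted.
    cutoffs : sequence of int
        Critical-illness cutoffs for which boolean flag columns are emitted.

    `transform` accepts a DataFrame with columns ``sbp``, ``pulse``, ``rr``,
    ``temp``, ``avpu`` and returns a DataFrame with ``mews_total`` plus one
    ``mews_critical_ge{c}`` column per cutoff.
    """

    def __init__(self, bands: Optional[ScoreBands] = None, cutoffs: Sequence[int] = (4, 5)):
        self.bands = bands
        self.cutoffs = cutoffs

    def fit(self, X, y=None):
        # rule-based: nothing to learn, but validate the band set once
        self.bands_ = self.bands or default_bands()
        self.bands_.validate()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "bands_"):
            self.fit(X)
        scored = score_frame(X, self.bands_, self.cutoffs)
        cols = ["mews_total"] + [f"mews_critical_ge{c}" for c in self.cutoffs]
        return scored[cols]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            ["mews_total"] + [f"mews_critical_ge{c}" for c in self.cutoffs], dtype=object
        )


class MEWSClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier: critical illness iff MEWS total >= cutoff.

    A fixed clinical rule rather than a learned model; `fit` only validates
    the configuration so the estimator plugs into sklearn tooling.
    `decision_function` exposes the raw total for ROC-style analyses.
    """

    def __init__(self, cutoff: int = 5, bands: Optional[ScoreBands] = None):
        self.cutoff = cutoff
        self.bands = bands

    def fit(self, X, y=None):
        if not (1 <= self.cutoff <= 14):
            raise ValueError(f"cutoff must be within 1-14, got {self.cutoff}")
        self.bands_ = self.bands or default_bands()
        self.classes_ = np.array([False, True])
        return self

    def _totals(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and "mews_total" in X.columns:
            return X["mews_total"].to_numpy()
        return score_frame(X, self.bands_)["mews_total"].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "bands_"):
            self.fit(X)
        return self._totals(X).astype(float)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) >= self.cutoff
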