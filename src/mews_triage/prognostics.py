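"""Prognostic accuracy of a MEWS cutoff against 7-day in-hospital mortality.

Everything here derives from the 2x2 table of cutoff classification
(test-positive: MEWS >= cutoff) versus vital status at day 7
(condition-positive: died in hospital within 7 days of assessment):

==============  =========  ==========
                died       survived
==============  =========  ==========
MEWS >= cutoff  tp         fp
MEWS <  cutoff  fn         tn
==============  =========  ==========

Patients discharged before day 7 are assumed alive; patients still on the
ward count as alive; self-discharged patients are excluded upstream.

Indicators: sensitivity, specificity, PPV, the positive likelihood ratio
with a log-method Wald interval, the number needed to evaluate
(NNE = 1/PPV, a workload proxy: patients reviewed per death detected), the
Wald odds ratio, and AUROC — for a single binary operating point the
trapezoidal area (sens + spec)/2 with a Hanley-McNeil standard error, and
for graded scores the Mann-Whitney form with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import as_frame

__all__ = [
    "TwoByTwo",
    "UndefinedIndicatorError",
    "build_two_by_two",
    "sensitivity",
    "specificity",
    "ppv",
    "lr_plus_ci",
    "nne",
    "odds_ratio_wald",
    "auroc_binary",
    "auroc_score",
    "PrognosticSummary",
    "prognostic_report",
    "cohort_comparison",
]

ALIVE_OUTCOMES = ("discharged", "on_ward")


class UndefinedIndicatorError(ZeroDivisionError):
    """An indicator's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of cutoff classification vs. death by day 7."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 or int(c) != c for c in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def deaths(self) -> int:
        return self.tp + self.fn

    @property
    def survivors(self) -> int:
        return self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp


class Interval(NamedTuple):
    lower: float
    upper: float


class RatioWithCI(NamedTuple):
    point: float
    ci: Interval


class ORResult(NamedTuple):
    point: float
    ci: Interval
    p: float
    corrected: bool  # Haldane-Anscombe +0.5 applied because of a zero cell


class AUROCResult(NamedTuple):
    area: float
    ci: Interval


def build_two_by_two(data, cutoff: int, score_col: str = "mews_total",
                     outcome_col: str = "outcome7") -> TwoByTwo:
    """Cross-tabulate score >= cutoff against died-by-day-7.

    ``data`` is a DataFrame (or sequence of PatientRecord) carrying MEWS
    totals and 7-day outcomes; outcomes must be ``died``, ``discharged`` or
    ``on_ward`` — self-discharged patients are excluded before this point.
    """
    frame = as_frame(data)
    if len(frame) == 0:
        raise ValueError("empty record list")
    outcomes = frame[outcome_col]
    bad = set(outcomes.unique()) - ({"died"} | set(ALIVE_OUTCOMES))
    if bad:
        raise ValueError(
            f"unexpected outcomes {sorted(bad)}: exclude self-discharged patients "
            "before building prognostic tables"
        )
    died = (outcomes == "died").to_numpy()
    positive = (frame[score_col].to_numpy() >= cutoff)
    return TwoByTwo(
        tp=int(np.sum(positive & died)),
        fp=int(np.sum(positive & ~died)),
        fn=int(np.sum(~positive & died)),
        tn=int(np.sum(~positive & ~died)),
    )


def sensitivity(t: TwoByTwo) -> float:
    """tp / (tp + fn) — the fraction of deaths flagged by the cutoff."""
    if t.deaths == 0:
        raise UndefinedIndicatorError("sensitivity undefined: no deaths in cohort")
    return t.tp / t.deaths


def specificity(t: TwoByTwo) -> float:
    """tn / (tn + fp) — the fraction of survivors not flagged."""
    if t.survivors == 0:
        raise UndefinedIndicatorError("specificity undefined: no survivors in cohort")
    return t.tn / t.survivors


def ppv(t: TwoByTwo) -> float:
    """tp / (tp + fp) — the fraction of flagged patients who died."""
    if t.positives == 0:
        raise UndefinedIndicatorError("PPV undefined: no test-positive patients")
    return t.tp / t.positives


def lr_plus_ci(t: TwoByTwo, level: float = 0.95) -> RatioWithCI:
    """Positive likelihood ratio sens/(1-spec) with the log-method CI.

    CI: ``exp(ln LR+ +/- z * sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)))``.
    With a zero cell the interval is unavailable (NaN bounds) but the point
    is still returned when defined.
    """
    sens, spec = sensitivity(t), specificity(t)
    if spec == 1.0:
        raise UndefinedIndicatorError("LR+ undefined: specificity is 1 (fp = 0 needed)")
    point = sens / (1.0 - spec)
    if t.tp == 0 or t.fp == 0:
        return RatioWithCI(point, Interval(math.nan, math.nan))
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / t.tp - 1 / t.deaths + 1 / t.fp - 1 / t.survivors)
    log_point = math.log(point)
    return RatioWithCI(
        point, Interval(math.exp(log_point - z * se), math.exp(log_point + z * se))
    )


def nne(t: TwoByTwo) -> float:
    """Number needed to evaluate, 1/PPV: patients reviewed per death found."""
    if t.tp == 0:
        raise UndefinedIndicatorError("NNE undefined: no true positives")
    return t.positives / t.tp


def odds_ratio_wald(t: TwoByTwo, level: float = 0.95) -> ORResult:
    """Cross-product odds ratio with Wald interval and two-sided p.

    OR = tp*tn / (fp*fn); CI = exp(ln OR +/- z*sqrt(1/tp+1/fp+1/fn+1/tn)).
    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    cells = [t.tp, t.fp, t.fn, t.tn]
    corrected = any(c == 0 for c in cells)
    if corrected:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    point = (a * d) / (b * c)
    se = math.sqrt(sum(1 / x for x in cells))
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_point = math.log(point)
    wald_z = log_point / se
    p = 2.0 * stats.norm.sf(abs(wald_z))
    return ORResult(
        point,
        Interval(math.exp(log_point - z * se), math.exp(log_point + z * se)),
        p,
        corrected,
    )


def auroc_binary(t: TwoByTwo, level: float = 0.95) -> AUROCResult:
    """AUROC of the binary cutoff rule: (sensitivity + specificity) / 2.

    The ROC of a single operating point is two line segments; the trapezoid
    area is the balanced accuracy.  The CI uses the Hanley-McNeil standard
    error with n1 deaths and n0 survivors.
    """
    if t.deaths == 0 or t.survivors == 0:
        raise ValueError("AUROC requires both deaths and survivors")
    area = (sensitivity(t) + specificity(t)) / 2.0
    n1, n0 = t.deaths, t.survivors
    q1 = area / (2.0 - area)
    q2 = 2.0 * area**2 / (1.0 + area)
    var = (
        area * (1 - area) + (n1 - 1) * (q1 - area**2) + (n0 - 1) * (q2 - area**2)
    ) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return AUROCResult(area, Interval(area - z * se, area + z * se))


def auroc_score(scores, died) -> float:
    """AUROC of a graded score: Mann-Whitney U / (n1*n0), ties as 1/2.

    Equals :func:`auroc_binary`'s area when the scores are themselves the
    0/1 cutoff flag.
    """
    scores = np.asarray(scores, dtype=float)
    died = np.asarray(died, dtype=bool)
    if scores.shape != died.shape:
        raise ValueError("scores and outcome flags must align")
    n1 = int(died.sum())
    n0 = int((~died).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both outcome classes")
    ranks = stats.rankdata(scores)
    u = ranks[died].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class PrognosticSummary:
    """All Table-5-style indicators for one cutoff on one cohort."""

    cutoff: int
    table: TwoByTwo
    sensitivity: float
    specificity: float
    ppv: float
    lr_plus: RatioWithCI
    nne: float
    or_: ORResult

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ppv"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} out of [0, 1]")


def prognostic_report(data, cutoffs: Sequence[int],
                      score_col: str = "mews_total") -> list[PrognosticSummary]:
    """One :class:`PrognosticSummary` per cutoff; deterministic."""
    out = []
    for cutoff in cutoffs:
        t = build_two_by_two(data, cutoff, score_col=score_col)
        out.append(
            PrognosticSummary(
                cutoff=cutoff,
                table=t,
                sensitivity=sensitivity(t),
                specificity=specificity(t),
                ppv=ppv(t),
                lr_plus=lr_plus_ci(t),
                nne=nne(t),
                or_=odds_ratio_wald(t),
            )
        )
    return out


# ---------------------------------------------------------------------------
# group comparison (analyzed vs. self-discharged, or any two cohorts)
# ---------------------------------------------------------------------------

DEFAULT_CONTINUOUS = ("age", "mews_total")
DEFAULT_CATEGORICAL = (
    "sex", "hiv", "attendant", "source", "service", "surgical_phase",
    "trauma", "mews_critical_ge4", "mews_critical_ge5",
)


def cohort_comparison(
    group_a,
    group_b,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> pd.DataFrame:
    """Feature-by-feature tests for a difference between two cohorts.

    Continuous features: two-sample t-test (Welch is not used; the pooled
    two-sample t matches the classical comparison).  Categorical features:
    chi-square test on the contingency table, switching automatically to
    Fisher's exact test when any expected cell count is below 5 (Fisher is
    only defined here for 2x2 layouts; larger sparse tables are noted).
    Degenerate (constant) features are skipped with a note.

    Returns a DataFrame with columns ``feature``, ``kind``, ``test``,
    ``statistic``, ``p``, ``note``.
    """
    a, b = as_frame(group_a), as_frame(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for feature in continuous:
        if feature not in a.columns or feature not in b.columns:
            continue
        x = a[feature].dropna().to_numpy(dtype=float)
        y = b[feature].dropna().to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((feature, "continuous", "skipped", math.nan, math.nan,
                         "constant feature"))
            continue
        res = stats.ttest_ind(x, y, equal_var=True)
        rows.append((feature, "continuous", "t-test", float(res.statistic),
                     float(res.pvalue), ""))
    for feature in categorical:
        if feature not in a.columns or feature not in b.columns:
            continue
        xa = a[feature].dropna().astype(str)
        xb = b[feature].dropna().astype(str)
        levels = sorted(set(xa.unique()) | set(xb.unique()))
        if len(levels) < 2:
            rows.append((feature, "categorical", "skipped", math.nan, math.nan,
                         "constant feature"))
            continue
        table = np.array([
            [int((xa == lv).sum()) for lv in levels],
            [int((xb == lv).sum()) for lv in levels],
        ])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table)
                rows.append((feature, "categorical", "fisher", math.nan, float(p),
                             "expected cell count < 5"))
                continue
            note = "expected cell count < 5; chi-square may be unreliable"
        else:
            note = ""
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append((feature, "categorical", "chi-square", float(chi2), float(p), note))
    return pd.DataFrame(
        rows, columns=["feature", "kind", "test", "statistic", "p", "note"]
    )
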