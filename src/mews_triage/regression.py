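"""Logistic regression for 7-day mortality.

Univariable screens (one single-predictor model per candidate, reported as
odds ratios with Wald intervals), a multivariable model with backward
stepwise elimination at a Wald-p threshold, deviance goodness-of-fit, and
model-based AUROC.

Maximum-likelihood fitting goes through iteratively reweighted least squares
(statsmodels GLM with a binomial family), converging when successive
log-likelihoods change by less than ``1e-8`` or after 100 iterations.
Records with missing covariates are dropped per model (complete-case), with
the exclusion count reported on the fit.  Quasi-separation is detected
(fitted probabilities within 1e-10 of 0/1 alongside a diverging
coefficient) and flags the fit as non-converged; singular designs are
rejected naming the collinear terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .prognostics import auroc_score
from .records import as_frame

__all__ = [
    "Predictor",
    "ModelSpec",
    "FittedModel",
    "LogisticModel",
    "fit_logistic",
    "univariable_screen",
    "backward_eliminate",
    "deviance_gof",
    "model_auroc",
    "GofResult",
]

_SEPARATION_PROB_TOL = 1e-10
_SEPARATION_COEF = 12.0


@dataclass(frozen=True)
class Predictor:
    """One model term with its coding.

    kind:
      - ``binary``: column coerced to a 0/1 indicator.
      - ``continuous``: entered untransformed, per unit.
      - ``categorical``: one indicator per non-reference level; ``reference``
        must name the baseline level.
    ``missing`` lists column values treated as unrecorded (e.g. ``unknown``
    HIV status), handled complete-case.
    """

    name: str
    kind: str = "binary"
    reference: Optional[str] = None
    missing: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical predictor {self.name!r} needs a reference level")


@dataclass(frozen=True)
class ModelSpec:
    """Binary response plus an ordered list of coded predictors."""

    outcome: str = "died"
    predictors: tuple = ()

    def __post_init__(self) -> None:
        preds = tuple(
            p if isinstance(p, Predictor) else Predictor(p) for p in self.predictors
        )
        object.__setattr__(self, "predictors", preds)
        names = [p.name for p in preds]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate predictors in model spec: {names}")

    def drop(self, name: str) -> "ModelSpec":
        return ModelSpec(
            self.outcome, tuple(p for p in self.predictors if p.name != name)
        )


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (collinear terms named)."""


def _outcome_vector(frame: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "died" and "outcome7" in frame.columns and "died" not in frame.columns:
        keep = frame["outcome7"] != "self_discharged"
        y = (frame.loc[keep, "outcome7"] == "died").astype(float)
        return y
    if outcome not in frame.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    return frame[outcome].astype(float)


def build_design(frame: pd.DataFrame, spec: ModelSpec):
    """Design matrix (with ``const``), response, term map and exclusion count.

    Returns ``(X, y, term_columns, n_excluded)`` where ``term_columns`` maps
    each predictor name to its design column names.
    """
    y = _outcome_vector(frame, spec.outcome)
    frame = frame.loc[y.index]
    columns: dict[str, pd.Series] = {}
    term_columns: dict[str, list[str]] = {}
    valid = pd.Series(True, index=frame.index)
    for pred in spec.predictors:
        if pred.name not in frame.columns:
            raise KeyError(f"predictor column {pred.name!r} not found")
        col = frame[pred.name]
        if pred.missing:
            valid &= ~col.isin(pred.missing)
        valid &= col.notna()
        if pred.kind == "categorical":
            levels = [lv for lv in sorted(col.dropna().astype(str).unique())
                      if lv != pred.reference and lv not in pred.missing]
            names = []
            for lv in levels:
                cname = f"{pred.name}[{lv}]"
                columns[cname] = (col.astype(str) == lv).astype(float)
                names.append(cname)
            term_columns[pred.name] = names
        elif pred.kind == "binary":
            columns[pred.name] = col.astype(bool).astype(float)
            term_columns[pred.name] = [pred.name]
        else:
            columns[pred.name] = col.astype(float)
            term_columns[pred.name] = [pred.name]
    X = pd.DataFrame(columns, index=frame.index) if columns else pd.DataFrame(index=frame.index)
    X.insert(0, "const", 1.0)
    n_total = len(frame)
    X, y = X.loc[valid], y.loc[valid]
    return X, y, term_columns, n_total - len(X)


@dataclass
class FittedModel:
    """A converged (or flagged) maximum-likelihood logistic fit."""

    spec: ModelSpec
    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    pvalues: np.ndarray
    deviance: float
    llf: float
    converged: bool
    n_used: int
    n_excluded: int
    term_columns: dict = field(default_factory=dict)
    _result: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.coefficients) == len(self.standard_errors)):
            raise ValueError("coefficient/SE/name lengths disagree")
        if self.deviance < -1e-8:
            raise ValueError("deviance must be non-negative")

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-term table: coefficient, SE, OR with Wald CI, p."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        coef, se = self.coefficients, self.standard_errors
        return pd.DataFrame(
            {
                "term": self.names,
                "coef": coef,
                "se": se,
                "or": np.exp(coef),
                "or_low": np.exp(coef - z * se),
                "or_high": np.exp(coef + z * se),
                "p": self.pvalues,
            }
        )

    def term_pvalue(self, term: str) -> float:
        """Joint Wald p for all design columns of one predictor."""
        cols = self.term_columns.get(term, [term])
        idx = [self.names.index(c) for c in cols]
        if len(idx) == 1:
            return float(self.pvalues[idx[0]])
        R = np.zeros((len(idx), len(self.names)))
        for row, j in enumerate(idx):
            R[row, j] = 1.0
        wt = self._result.wald_test(R, scalar=True)
        return float(wt.pvalue)

    def linear_predictor(self, data) -> np.ndarray:
        frame = as_frame(data)
        X, _, _, _ = build_design(frame, self.spec)
        X = X[self.names]
        return X.to_numpy() @ self.coefficients

    def predict_proba(self, data) -> np.ndarray:
        eta = self.linear_predictor(data)
        return 1.0 / (1.0 + np.exp(-eta))


def _check_design(X: pd.DataFrame) -> None:
    non_const = [c for c in X.columns if c != "const"]
    constant = [c for c in non_const if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(arr)
        small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        bad = [c for c, s in zip(X.columns, small) if s]
        raise SingularDesignError(f"singular design; collinear terms: {bad or list(X.columns)}")


def _fit_glm(X: pd.DataFrame, y: pd.Series, tol: float = 1e-8, maxiter: int = 100):
    _check_design(X)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; cannot fit")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    # deviance = -2*llf + const, so a deviance change < 2*tol bounds the llf change
    result = model.fit(maxiter=maxiter, tol=tol)
    mu = np.asarray(result.fittedvalues)
    separated = (
        ((mu < _SEPARATION_PROB_TOL) | (mu > 1 - _SEPARATION_PROB_TOL)).any()
        and np.abs(result.params.to_numpy()).max() > _SEPARATION_COEF
    )
    converged = bool(result.converged) and not separated
    return result, converged


def fit_logistic(data, spec: ModelSpec, tol: float = 1e-8, maxiter: int = 100) -> FittedModel:
    """Maximum-likelihood logistic fit of the spec on a patient table."""
    frame = as_frame(data)
    X, y, term_columns, n_excluded = build_design(frame, spec)
    if len(X) == 0:
        raise ValueError("no usable records after complete-case filtering")
    result, converged = _fit_glm(X, y, tol=tol, maxiter=maxiter)
    return FittedModel(
        spec=spec,
        names=list(X.columns),
        coefficients=result.params.to_numpy(),
        standard_errors=result.bse.to_numpy(),
        pvalues=result.pvalues.to_numpy(),
        deviance=float(result.deviance),
        llf=float(result.llf),
        converged=converged,
        n_used=len(X),
        n_excluded=n_excluded,
        term_columns=term_columns,
        _result=result,
    )


def univariable_screen(data, predictors: Sequence[Union[str, Predictor]],
                       outcome: str = "died") -> pd.DataFrame:
    """One single-predictor logistic model per candidate.

    Returns a per-design-column table of unadjusted ORs with 95% Wald CIs
    and p-values; predictors that cannot be fit (constant, separated) are
    reported inline with a note rather than aborting the screen.
    """
    frame = as_frame(data)
    rows = []
    for pred in predictors:
        pred = pred if isinstance(pred, Predictor) else Predictor(pred)
        try:
            fitted = fit_logistic(frame, ModelSpec(outcome, (pred,)))
        except (ValueError, KeyError) as exc:
            rows.append({"term": pred.name, "or": math.nan, "or_low": math.nan,
                         "or_high": math.nan, "p": math.nan, "n_used": 0,
                         "note": f"skipped: {exc}"})
            continue
        tab = fitted.summary()
        note = "" if fitted.converged else "non-converged (possible separation)"
        for _, r in tab[tab["term"] != "const"].iterrows():
            rows.append({"term": r["term"], "or": r["or"], "or_low": r["or_low"],
                         "or_high": r["or_high"], "p": r["p"],
                         "n_used": fitted.n_used, "note": note})
    return pd.DataFrame(rows, columns=["term", "or", "or_low", "or_high", "p",
                                       "n_used", "note"])


def backward_eliminate(data, spec: ModelSpec, alpha: float = 0.05):
    """Backward stepwise elimination at a Wald-p threshold.

    Repeatedly refits, removing the predictor with the largest joint Wald p
    at or above ``alpha``, until every remaining term is below the
    threshold.  Exact p ties are broken by declared predictor order (the
    later-declared term is removed).  Returns ``(final_model, trace)`` where
    each trace entry is ``(removed_term, p_at_removal)``; an intercept-only
    model is returned if everything is eliminated.
    """
    if not (0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    frame = as_frame(data)
    current = spec
    trace: list[tuple[str, float]] = []
    fitted = fit_logistic(frame, current)
    while current.predictors:
        pvals = [(p.name, fitted.term_pvalue(p.name)) for p in current.predictors]
        worst_p = max(p for _, p in pvals)
        if worst_p < alpha:
            break
        # last-declared among exact ties is dropped
        worst_name = [name for name, p in pvals if p == worst_p][-1]
        trace.append((worst_name, worst_p))
        current = current.drop(worst_name)
        fitted = fit_logistic(frame, current)
    return fitted, trace


@dataclass(frozen=True)
class GofResult:
    """Grouped-deviance goodness of fit over distinct covariate patterns."""

    chi2: float
    df: int
    p: float
    n_patterns: int
    raw_deviance: float


def deviance_gof(model: FittedModel, data) -> GofResult:
    """Deviance of the fit against the covariate-pattern saturated model.

    Observations sharing a covariate pattern are pooled into binomial cells;
    the grouped deviance is compared to chi-square with
    ``patterns - parameters`` degrees of freedom.  The raw (individual-level)
    residual deviance is carried alongside for reference.
    """
    if not model.converged:
        raise ValueError("goodness of fit requires a converged model")
    frame = as_frame(data)
    X, y, _, _ = build_design(frame, model.spec)
    X = X[model.names]
    eta = X.to_numpy() @ model.coefficients
    mu = 1.0 / (1.0 + np.exp(-eta))
    key = pd.util.hash_pandas_object(X, index=False).to_numpy()
    grouped = pd.DataFrame({"key": key, "y": y.to_numpy(), "mu": mu}).groupby("key")
    obs = grouped["y"].sum().to_numpy()
    n = grouped["y"].count().to_numpy()
    fit = grouped["mu"].sum().to_numpy()  # expected deaths per pattern
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(obs > 0, obs * np.log(obs / fit), 0.0)
        term2 = np.where(n - obs > 0, (n - obs) * np.log((n - obs) / (n - fit)), 0.0)
    chi2 = float(2.0 * (term1 + term2).sum())
    df = int(len(obs) - len(model.coefficients))
    if df <= 0:
        raise ValueError(
            f"goodness of fit undefined: {len(obs)} covariate patterns, "
            f"{len(model.coefficients)} parameters"
        )
    return GofResult(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        n_patterns=int(len(obs)),
        raw_deviance=model.deviance,
    )


def model_auroc(model: FittedModel, data) -> float:
    """Discrimination of the fitted model: AUROC of its linear predictor."""
    if not model.converged:
        raise ValueError("AUROC requires a converged model")
    frame = as_frame(data)
    X, y, _, _ = build_design(frame, model.spec)
    eta = X[model.names].to_numpy() @ model.coefficients
    return auroc_score(eta, y.to_numpy().astype(bool))


class LogisticModel(BaseEstimator):
    """sklearn-style wrapper around the mortality logistic regression.

    Parameters
    ----------
    predictors : sequence of str or Predictor
        Model terms; column names of the patient table.
    outcome : str
        Binary response column (``died`` is derived from ``outcome7``).
    backward : bool
        Apply backward stepwise elimination after the initial fit.
    alpha : float
        Wald-p removal threshold for elimination.

    After ``fit(data)``: ``model_`` (the :class:`FittedModel`), ``trace_``
    (elimination steps), ``coef_``, ``names_``.  ``predict_proba`` and
    ``decision_function`` evaluate the fitted linear predictor.
    """

    def __init__(self, predictors=(), outcome: str = "died",
                 backward: bool = False, alpha: float = 0.05):
        self.predictors = predictors
        self.outcome = outcome
        self.backward = backward
        self.alpha = alpha

    def fit(self, X, y=None):
        frame = as_frame(X)
        spec = ModelSpec(self.outcome, tuple(self.predictors))
        if self.backward:
            self.model_, self.trace_ = backward_eliminate(frame, spec, self.alpha)
        else:
            self.model_ = fit_logistic(frame, spec)
            self.trace_ = []
        self.names_ = self.model_.names
        self.coef_ = self.model_.coefficients
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.model_.linear_predictor(X)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.model_.predict_proba(X) >= 0.5

    def summary(self) -> pd.DataFrame:
        return self.model_.summary()
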