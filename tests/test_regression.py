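"""Logistic regression, backward elimination, deviance GOF, model AUROC."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mews_triage import (CohortParams, ModelSpec, Predictor, backward_eliminate,
                         build_two_by_two, deviance_gof, fit_logistic,
                         generate_cohort, model_auroc, odds_ratio_wald,
                         univariable_screen, LogisticModel, auroc_binary)
from mews_triage.regression import SingularDesignError, build_design
from mews_triage.scoring import score_frame

MEWS5 = Predictor("mews_critical_ge5")
MEDICAL = Predictor("service", "categorical", reference="surgical")


@pytest.fixture(scope="module")
def cohort_20k():
    return score_frame(generate_cohort(CohortParams(n=20_000, seed=99)))


def test_single_binary_predictor_equals_cross_product_or(ref):
    """One-predictor logistic ML OR is algebraically the 2x2 OR."""
    for cutoff, flag in ((4, "mews_critical_ge4"), (5, "mews_critical_ge5")):
        fitted = fit_logistic(ref, ModelSpec("died", (Predictor(flag),)))
        table = fitted.summary().set_index("term")
        expected = odds_ratio_wald(build_two_by_two(ref, cutoff))
        assert table.loc[flag, "or"] == pytest.approx(expected.point, abs=1e-6)
        assert table.loc[flag, "or_low"] == pytest.approx(expected.ci.lower, rel=1e-6)
        assert table.loc[flag, "or_high"] == pytest.approx(expected.ci.upper, rel=1e-6)
        # p is an exponentially sensitive function of z; IRLS convergence at
        # 1e-8 in the log-likelihood leaves ~1e-5 relative slack here
        assert table.loc[flag, "p"] == pytest.approx(expected.p, rel=1e-4)


def test_intercept_only_model_closed_form(ref):
    fitted = fit_logistic(ref, ModelSpec("died", ()))
    assert fitted.coefficients[0] == pytest.approx(math.log(25 / 427), abs=1e-8)
    assert fitted.n_used == 452


def test_univariable_screen_reproduces_published_table(ref):
    screen = univariable_screen(
        ref,
        [Predictor("mews_critical_ge4"), Predictor("mews_critical_ge5"),
         MEDICAL, Predictor("trauma"),
         Predictor("sex", "categorical", reference="male"),
         Predictor("hiv", "categorical", reference="negative", missing=("unknown",))],
    ).set_index("term")
    published = {
        "mews_critical_ge4": (5.35, 2.35, 12.23),
        "mews_critical_ge5": (8.69, 3.72, 20.29),
        "service[medical]": (9.87, 2.91, 33.5),
        "trauma": (0.57, 0.17, 1.96),
        "sex[female]": (0.89, 0.39, 2.01),
        "hiv[positive]": (4.23, 1.64, 10.93),
    }
    for term, (point, low, high) in published.items():
        row = screen.loc[term]
        # one unit of printed precision: some source bounds are truncated
        # rather than rounded (e.g. female-sex lower bound 0.3958 -> "0.39")
        assert row["or"] == pytest.approx(point, abs=5e-3), term
        assert row["or_low"] == pytest.approx(low, abs=0.01), term
        assert row["or_high"] == pytest.approx(high, abs=0.05), term
    assert screen.loc["hiv[positive]", "n_used"] == 338  # complete-case


def test_univariable_screen_skips_constant_predictor(ref):
    frame = ref.copy()
    frame["hdu"] = False
    screen = univariable_screen(frame, [Predictor("hdu"), MEWS5])
    assert screen.set_index("term").loc["hdu", "note"].startswith("skipped")
    assert math.isnan(screen.set_index("term").loc["hdu", "or"])


def test_parameter_recovery_within_3_se(cohort_20k):
    fitted = fit_logistic(cohort_20k, ModelSpec("died", (MEWS5, MEDICAL)))
    truth = {"mews_critical_ge5": math.log(5.82), "service[medical]": math.log(7.17)}
    table = fitted.summary().set_index("term")
    for term, beta in truth.items():
        err = abs(table.loc[term, "coef"] - beta)
        assert err < 3 * table.loc[term, "se"], term


def test_null_predictor_ci_coverage():
    """A predictor independent of outcome: 95% CI covers 1 in ~95% of reps."""
    rng = np.random.default_rng(321)
    n, reps, covered = 600, 150, 0
    for _ in range(reps):
        frame = pd.DataFrame({
            "died": rng.random(n) < 0.12,
            "noise": rng.random(n) < 0.4,
        })
        fitted = fit_logistic(frame, ModelSpec("died", (Predictor("noise"),)))
        row = fitted.summary().set_index("term").loc["noise"]
        covered += row["or_low"] <= 1.0 <= row["or_high"]
    # binomial(150, .95): 3 SE band is about +/- 0.053
    assert 0.89 <= covered / reps <= 1.0


def test_backward_elimination_drops_noise_keeps_signal(cohort_20k):
    frame = cohort_20k.copy()
    rng = np.random.default_rng(12)
    frame["noise"] = rng.random(len(frame)) < 0.5
    spec = ModelSpec("died", (MEWS5, MEDICAL, Predictor("noise")))
    fitted, trace = backward_eliminate(frame, spec, alpha=0.05)
    assert [t for t, _ in trace] == ["noise"]
    assert {p.name for p in fitted.spec.predictors} == {"mews_critical_ge5", "service"}
    assert all(fitted.term_pvalue(p.name) < 0.05 for p in fitted.spec.predictors)


def test_backward_elimination_no_removals_when_all_significant(ref):
    spec = ModelSpec("died", (MEWS5, MEDICAL))
    fitted, trace = backward_eliminate(ref, spec, alpha=0.05)
    assert trace == []
    assert {p.name for p in fitted.spec.predictors} == {"mews_critical_ge5", "service"}


def test_backward_elimination_alpha_one_never_removes(ref):
    spec = ModelSpec("died", (MEWS5, MEDICAL, Predictor("trauma"),
                              Predictor("sex", "categorical", reference="male")))
    _, trace = backward_eliminate(ref, spec, alpha=1.0)
    assert trace == []


def test_backward_elimination_all_terms_out(ref):
    rng = np.random.default_rng(3)
    frame = ref.copy()
    frame["noise_a"] = rng.random(len(frame)) < 0.5
    frame["noise_b"] = rng.random(len(frame)) < 0.5
    fitted, trace = backward_eliminate(
        frame, ModelSpec("died", (Predictor("noise_a"), Predictor("noise_b"))), 0.05
    )
    assert fitted.spec.predictors == ()
    assert len(trace) == 2
    assert fitted.names == ["const"]


def test_elimination_invariant_to_input_order(cohort_20k):
    frame = cohort_20k.copy()
    rng = np.random.default_rng(12)
    frame["noise"] = rng.random(len(frame)) < 0.5
    preds = (MEWS5, MEDICAL, Predictor("noise"))
    final_a, _ = backward_eliminate(frame, ModelSpec("died", preds), 0.05)
    final_b, _ = backward_eliminate(frame, ModelSpec("died", preds[::-1]), 0.05)
    assert {p.name for p in final_a.spec.predictors} == \
        {p.name for p in final_b.spec.predictors}


def test_separation_flagged_nonconverged():
    frame = pd.DataFrame({
        "died": [True] * 10 + [False] * 10,
        "flag": [True] * 10 + [False] * 10,
    })
    fitted = fit_logistic(frame, ModelSpec("died", (Predictor("flag"),)))
    assert not fitted.converged


def test_singular_design_rejected_naming_terms(ref):
    frame = ref.copy()
    frame["dup"] = frame["mews_critical_ge5"]
    spec = ModelSpec("died", (MEWS5, Predictor("dup")))
    with pytest.raises(SingularDesignError, match="dup"):
        fit_logistic(frame, spec)


def test_duplicate_predictors_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ModelSpec("died", (MEWS5, Predictor("mews_critical_ge5", "binary")))


def test_grouped_deviance_matches_grouped_binomial_glm(ref):
    """Independent route: statsmodels fit on pattern-pooled binomial cells."""
    fitted = fit_logistic(ref, ModelSpec("died", (MEWS5, MEDICAL)))
    gof = deviance_gof(fitted, ref)
    X, y, _, _ = build_design(ref, fitted.spec)
    cells = pd.concat([X, y.rename("y")], axis=1).groupby(list(X.columns))
    grouped = cells["y"].agg(["sum", "count"]).reset_index()
    endog = np.column_stack([grouped["sum"], grouped["count"] - grouped["sum"]])
    exog = grouped[[c for c in X.columns]].to_numpy()
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    assert gof.chi2 == pytest.approx(res.deviance, abs=1e-6)
    assert gof.n_patterns == len(grouped)
    assert gof.df == gof.n_patterns - len(fitted.coefficients)
    assert 0.0 <= gof.p <= 1.0


def test_deviance_gof_df_guard(ref):
    # one binary predictor: 2 patterns, 2 parameters -> df 0, undefined
    fitted = fit_logistic(ref, ModelSpec("died", (MEWS5,)))
    with pytest.raises(ValueError, match="covariate patterns"):
        deviance_gof(fitted, ref)


def test_deviance_gof_calibration_under_true_model():
    """p-values roughly uniform when the fitted model is the generator."""
    from scipy import stats

    pvals = []
    for rep in range(100):
        cohort = score_frame(generate_cohort(CohortParams(n=2_000, seed=10_000 + rep)))
        fitted = fit_logistic(cohort, ModelSpec("died", (MEWS5, MEDICAL)))
        pvals.append(deviance_gof(fitted, cohort).p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_deviance_gof_power_against_misspecification():
    """An omitted strong interaction shows up as lack of fit at large n."""
    rng = np.random.default_rng(5)
    n = 20_000
    x1 = rng.random(n) < 0.5
    x2 = rng.random(n) < 0.5
    eta = -2.0 + 1.0 * x1 + 1.0 * x2 + 1.5 * (x1 & x2)
    frame = pd.DataFrame({
        "died": rng.random(n) < 1 / (1 + np.exp(-eta)),
        "x1": x1,
        "x2": x2,
    })
    fitted = fit_logistic(frame, ModelSpec("died", (Predictor("x1"), Predictor("x2"))))
    gof = deviance_gof(fitted, frame)  # main-effects model omits the interaction
    assert gof.p < 0.01


def test_model_auroc_single_flag_equals_binary_auroc(ref):
    fitted = fit_logistic(ref, ModelSpec("died", (MEWS5,)))
    area = model_auroc(fitted, ref)
    assert area == pytest.approx(auroc_binary(build_two_by_two(ref, 5)).area, abs=1e-12)
    assert area == pytest.approx(0.692, abs=5e-4)


def test_model_auroc_useless_predictor_near_half(cohort_20k):
    frame = cohort_20k.copy()
    rng = np.random.default_rng(8)
    frame["noise"] = rng.random(len(frame)) < 0.5
    fitted = fit_logistic(frame, ModelSpec("died", (Predictor("noise"),)))
    assert model_auroc(fitted, frame) == pytest.approx(0.5, abs=0.03)


def test_model_auroc_matches_pairwise_enumeration(ref):
    fitted = fit_logistic(ref, ModelSpec("died", (MEWS5, MEDICAL)))
    X, y, _, _ = build_design(ref, fitted.spec)
    eta = X[fitted.names].to_numpy() @ fitted.coefficients
    died = y.to_numpy().astype(bool)
    pairs = sum(
        1.0 if d > a else 0.5 if d == a else 0.0
        for d in eta[died] for a in eta[~died]
    )
    expected = pairs / (died.sum() * (~died).sum())
    assert model_auroc(fitted, ref) == pytest.approx(expected, abs=1e-12)


def test_loglikelihood_nondecreasing_after_convergence(ref):
    # refitting from the converged coefficients cannot lower the likelihood
    fitted = fit_logistic(ref, ModelSpec("died", (MEWS5, MEDICAL)))
    X, y, _, _ = build_design(ref, fitted.spec)
    res0 = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=1)
    assert fitted.llf >= float(res0.llf) - 1e-9


def test_sklearn_estimator_wrapper(ref):
    model = LogisticModel(predictors=(MEWS5, MEDICAL), backward=True).fit(ref)
    assert model.trace_ == []
    proba = model.predict_proba(ref)
    assert proba.shape == (452, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    params = model.get_params()
    assert params["alpha"] == 0.05
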