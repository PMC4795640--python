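# mews-triage

Ward-triage analysis with the Modified Early Warning Score (MEWS), built for
epidemiologists and clinicians studying recognition of critical illness on
general hospital wards — particularly in resource-limited settings where the
score's five bedside inputs (systolic blood pressure, pulse, respiratory
rate, axillary temperature, AVPU consciousness level) may be the only
severity measure available.

## What it computes

**Scoring.** Each vital sign maps to an integer subscore through a banded
rule; the MEWS is the sum,

    MEWS = s_SBP + s_pulse + s_RR + s_temp + s_AVPU,   0 <= MEWS <= 14,

and a patient is classified *critically ill* when MEWS >= c (c = 5 by
convention; c = 4 is the standard alternative). The band rule is data, not
code: alternative boundary conventions load from YAML/JSON.

**Prognostic accuracy.** Against 7-day in-hospital mortality, each cutoff c
yields a 2x2 table (tp, fp, fn, tn) from which the package derives
sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp), the
positive likelihood ratio LR+ = sens/(1-spec) with a log-method Wald CI,
the number needed to evaluate NNE = 1/PPV (patients reviewed per death
detected — a workload proxy), the cross-product odds ratio with Wald CI
exp(ln OR ± z·sqrt(1/tp+1/fp+1/fn+1/tn)), and AUROC — (sens+spec)/2 for the
single operating point, the tie-aware Mann–Whitney form for graded scores.

**Regression.** Univariable logistic screens, a multivariable mortality
model with backward stepwise elimination at a Wald-p threshold, grouped
deviance goodness of fit, and model-based AUROC. Estimators follow sklearn
conventions (`MEWSScorer`, `MEWSClassifier`, `LogisticModel`).

**Synthetic cohorts.** A seeded generator emulating a single-assessment
ward cohort: MEWS totals drawn from an explicit mass (median 2, IQR 1–3,
P(MEWS>=5) = 0.117), mortality from a logistic model in MEWS >= 5
(OR 5.82) and medical admission (OR 7.17) calibrated to 5.5% marginal
7-day mortality, vitals inverse-sampled so every record re-scores to its
drawn total, and an optional severity-shifted self-discharge arm.

## Worked example

```python
>>> import mews_triage as mt
>>> v = mt.VitalSigns(sbp=85, pulse=115, rr=22, temp=34.5, avpu="V")
>>> mt.compute_mews(v)
MEWSBreakdown(sub_sbp=1, sub_pulse=2, sub_rr=2, sub_temp=2, sub_avpu=1, total=8)

>>> cohort = mt.reference_cohort()      # published-margin reconstruction, n=452
>>> t5 = mt.build_two_by_two(cohort, 5)
>>> t5
TwoByTwo(tp=12, fp=41, fn=13, tn=386)
>>> round(mt.sensitivity(t5), 4), round(mt.specificity(t5), 4)
(0.48, 0.904)
>>> mt.lr_plus_ci(t5).point
4.999024390243902
>>> round(mt.nne(t5), 2)
4.42
>>> o = mt.odds_ratio_wald(t5); round(o.point, 2), tuple(round(x, 2) for x in o.ci)
(8.69, (3.72, 20.29))
>>> round(mt.auroc_binary(t5).area, 3)
0.692
```

A MEWS of 5 or greater flags 53/452 patients (11.7%), catches 48% of the
25 deaths while wrongly flagging under 10% of survivors, multiplies the
odds of death by ~8.7, and requires evaluating ~4.4 flagged patients per
death detected.

The same pipeline from the shell:

```sh
mews-triage simulate --n 452 --seed 7 --out cohort.csv
mews-triage score    --in cohort.csv  --out scored.csv
mews-triage evaluate --in scored.csv  --cutoffs 4,5 --out report.tsv
mews-triage model    --in scored.csv  --out model.json \
    --predictors mews_critical_ge5,service:categorical:surgical --backward --auroc
```

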