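"""Seeded synthetic ward cohorts with the study's statistical structure.

The generator emulates a single-assessment ward cohort: one MEWS
observation per adult patient, a 7-day in-hospital outcome, and the
admission covariates the mortality analysis uses.  Mortality follows a
logistic model in the critical-illness flag (MEWS >= 5) and medical
service, with the intercept calibrated so the marginal death probability
hits a target (5.5% by default); the MEWS total itself is drawn from an
explicit probability mass over 0-9 whose median is 2 (IQR 1-3) with
P(>=4) = 0.212 and P(>=5) = 0.117.  Vitals are sampled *backwards* from the
drawn total, uniformly over the integer compositions achievable under the
banded rule and then uniformly within each band, so every generated record
re-scores to its drawn total exactly.

Within-band correlations between vital signs are not modelled: the cohort
reproduces band membership, not physiology.

:func:`reference_cohort` is different in kind: a deterministic synthetic
reconstruction of the source study's published margins (2x2 mortality
tables and univariable risk-factor counts), used as the desk-scale fixture
for the prognostic indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .bands import SCORED_PARAMETERS, Band, ScoreBands, default_bands
from .records import ER_FLAGS, SOURCES, VitalSigns

__all__ = [
    "CohortParams",
    "DEFAULT_MEWS_PMF",
    "calibrate_intercept",
    "sample_vitals_for_total",
    "generate_cohort",
    "reference_cohort",
]

#: Default mass over MEWS totals 0-9 (explicit constants, not fitted):
#: median 2, IQR 1-3, P(>=4) = 0.212, P(>=5) = 0.117.
DEFAULT_MEWS_PMF = (0.12, 0.22, 0.24, 0.208, 0.095, 0.055, 0.030, 0.016, 0.010, 0.006)


@dataclass(frozen=True)
class CohortParams:
    """Full generative specification of a synthetic ward cohort.

    Defaults are calibrated to the analyzed source cohort's published
    structure; the optional self-discharge arm (off by default, enable via
    :meth:`with_self_discharge`) adds censoring-by-self-discharge with a
    severity shift (more medical, more HIV-positive, higher MEWS).
    """

    n: int = 452
    seed: int = 0
    p_medical: float = 0.451
    mews_pmf: tuple = DEFAULT_MEWS_PMF
    beta_mews5: float = math.log(5.82)
    beta_medical: float = math.log(7.17)
    beta_hiv: float = 0.0  # optional HIV-positive log-OR, e.g. ln(4.23)
    target_mortality: float = 0.055
    p_hiv_missing: float = 0.252
    p_hiv_pos_known: float = 0.325
    p_male: float = 0.533
    p_trauma: float = 0.188
    p_attendant: float = 0.894
    p_preop_given_surgical: float = 0.541
    source_probs: tuple = (0.538, 0.300, 0.162)  # emergency, government, private
    age_mean: float = 42.8
    age_sd: float = 16.6
    los_median_days: float = 9.0
    los_log_sd: float = 1.33
    p_discharged_given_alive: float = 0.438
    er_doc_probs: tuple = (0.30, 0.35, 0.15, 0.10, 0.20)  # hr, bp, rr, spo2, gcs
    selfdischarge_rate: float = 0.0
    sd_p_medical: float = 0.65
    sd_p_hiv_pos_known: float = 0.50
    sd_mews_tilt: float = 1.35  # pmf tilted by tilt**total for the censored arm

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        pmf = tuple(float(p) for p in self.mews_pmf)
        if len(pmf) > 15:
            raise ValueError("mews_pmf support must lie within totals 0-14")
        if any(p < 0 for p in pmf) or abs(sum(pmf) - 1.0) > 1e-9:
            raise ValueError("mews_pmf must be a probability mass summing to 1")
        object.__setattr__(self, "mews_pmf", pmf)
        for name in ("p_medical", "target_mortality", "p_hiv_missing",
                     "p_hiv_pos_known", "p_male", "p_trauma", "p_attendant",
                     "p_preop_given_surgical", "p_discharged_given_alive",
                     "selfdischarge_rate", "sd_p_medical", "sd_p_hiv_pos_known"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if abs(sum(self.source_probs) - 1.0) > 1e-9:
            raise ValueError("source_probs must sum to 1")

    def with_self_discharge(self, rate: float = 62.0 / 530.0) -> "CohortParams":
        """Enable the severity-shifted self-discharge (censoring) arm."""
        return replace(self, selfdischarge_rate=rate)

    @property
    def p_mews5(self) -> float:
        return float(sum(self.mews_pmf[5:]))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def calibrate_intercept(params: CohortParams) -> float:
    """Log-odds intercept matching the marginal death probability target.

    Solves ``E[sigmoid(b0 + beta.x)] = target_mortality`` over the discrete
    covariate distribution (MEWS>=5, service, optionally HIV+), by bisection
    to 1e-10.
    """
    t = params.target_mortality
    if not (0.0 < t < 1.0):
        raise ValueError(
            f"target_mortality = {t} unattainable; feasible range is (0, 1) exclusive"
        )
    p5 = params.p_mews5
    p_hiv = (1.0 - params.p_hiv_missing) * params.p_hiv_pos_known
    cells = []
    for m5, med, hiv in product((0, 1), repeat=3):
        w = ((p5 if m5 else 1 - p5)
             * (params.p_medical if med else 1 - params.p_medical)
             * (p_hiv if hiv else 1 - p_hiv))
        eta = m5 * params.beta_mews5 + med * params.beta_medical + hiv * params.beta_hiv
        cells.append((w, eta))

    def marginal(b0: float) -> float:
        return float(sum(w * _sigmoid(b0 + eta) for w, eta in cells)) - t

    return float(optimize.brentq(marginal, -60.0, 60.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# vitals <-> total inversion
# ---------------------------------------------------------------------------


def _compositions(total: int, bands: ScoreBands) -> list[tuple[int, ...]]:
    """Subscore 5-tuples (sbp, pulse, rr, temp, avpu) summing to ``total``."""
    choices = [bands.achievable_subscores(p) for p in SCORED_PARAMETERS]
    return [c for c in product(*choices) if sum(c) == total]


def _band_grid(band: Band, parameter: str, top: bool) -> np.ndarray:
    """Admissible measurement grid inside one band (integers; temp to 0.1)."""
    if parameter == "temp":
        grid = np.round(np.arange(band.lo, band.hi + 1e-9, 0.1), 1)
        keep = grid < band.hi if not top else grid <= band.hi
        return grid[keep]
    lo = int(math.ceil(band.lo))
    hi = int(math.ceil(band.hi))  # [lo, hi) over integers
    if top:
        hi = int(band.hi) + 1
    return np.arange(lo, hi, dtype=float)


def _grids_by_score(bands: ScoreBands) -> dict:
    """(parameter, subscore) -> list of value grids (one per matching band)."""
    out: dict = {}
    for parameter in ("sbp", "pulse", "rr", "temp"):
        blist = bands.bands_for(parameter)
        ordered = sorted(blist, key=lambda b: b.lo)
        for band in blist:
            top = band is ordered[-1]
            out.setdefault((parameter, band.score), []).append(
                _band_grid(band, parameter, top)
            )
    for score in set(bands.avpu_map.values()):
        letters = sorted(k for k, v in bands.avpu_map.items() if v == score)
        out[("avpu", score)] = [np.array(letters, dtype=object)]
    return out


def sample_vitals_for_total(total: int, bands: Optional[ScoreBands] = None,
                            rng: Optional[np.random.Generator] = None) -> VitalSigns:
    """Draw vitals whose MEWS re-scores exactly to ``total``.

    A subscore composition is drawn uniformly from those achievable under
    the band rule's per-parameter maxima, then each measurement is drawn
    uniformly within a band carrying that subscore (unbounded printed bands
    are truncated at the admissible-range edge).
    """
    bands = bands or default_bands()
    rng = rng or np.random.default_rng()
    comps = _compositions(int(total), bands)
    if not comps:
        raise ValueError(f"MEWS total {total} is not achievable under these bands")
    comp = comps[rng.integers(len(comps))]
    grids = _grids_by_score(bands)
    values = {}
    for parameter, score in zip(SCORED_PARAMETERS, comp):
        options = grids[(parameter, score)]
        grid = options[rng.integers(len(options))] if len(options) > 1 else options[0]
        values[parameter] = grid[rng.integers(len(grid))]
    return VitalSigns(
        sbp=float(values["sbp"]), pulse=float(values["pulse"]), rr=float(values["rr"]),
        temp=float(values["temp"]), avpu=str(values["avpu"]),
    )


def _sample_vitals_batch(totals: np.ndarray, bands: ScoreBands,
                         rng: np.random.Generator):
    """Vectorized inverse sampling; returns dict of vital-sign arrays."""
    n = len(totals)
    comps_by_total = {int(t): np.array(_compositions(int(t), bands))
                      for t in np.unique(totals)}
    subs = np.zeros((n, 5), dtype=int)
    for t in sorted(comps_by_total):
        idx = np.flatnonzero(totals == t)
        comps = comps_by_total[t]
        if len(comps) == 0:
            raise ValueError(f"MEWS total {t} is not achievable under these bands")
        subs[idx] = comps[rng.integers(len(comps), size=len(idx))]
    grids = _grids_by_score(bands)
    out: dict[str, np.ndarray] = {}
    for j, parameter in enumerate(SCORED_PARAMETERS):
        col = np.empty(n, dtype=object if parameter == "avpu" else float)
        for score in np.unique(subs[:, j]):
            idx = np.flatnonzero(subs[:, j] == score)
            options = grids[(parameter, int(score))]
            if len(options) > 1:
                which = rng.integers(len(options), size=len(idx))
            else:
                which = np.zeros(len(idx), dtype=int)
            for k, grid in enumerate(options):
                sel = idx[which == k]
                col[sel] = grid[rng.integers(len(grid), size=len(sel))]
        out[parameter] = col
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(params: CohortParams,
                    bands: Optional[ScoreBands] = None) -> pd.DataFrame:
    """Generate a seeded synthetic patient table (one row per patient).

    Identical params + seed yield an identical table.  Columns follow the
    standard patient CSV schema; MEWS totals are *not* included — rescoring
    the emitted vitals recovers them exactly (round-trip property).
    """
    bands = bands or default_bands()
    rng = np.random.default_rng(params.seed)
    n = params.n
    pmf = np.array(params.mews_pmf)
    support = np.arange(len(pmf))

    selfd = rng.random(n) < params.selfdischarge_rate
    # severity-shifted parameters for the censored arm
    p_med = np.where(selfd, params.sd_p_medical, params.p_medical)
    medical = rng.random(n) < p_med
    tilted = pmf * params.sd_mews_tilt ** support
    tilted /= tilted.sum()
    totals = np.where(
        selfd,
        rng.choice(support, size=n, p=tilted),
        rng.choice(support, size=n, p=pmf),
    )
    hiv_missing = rng.random(n) < params.p_hiv_missing
    p_pos = np.where(selfd, params.sd_p_hiv_pos_known, params.p_hiv_pos_known)
    hiv_pos = rng.random(n) < p_pos
    hiv = np.where(hiv_missing, "unknown", np.where(hiv_pos, "positive", "negative"))

    sex = np.where(rng.random(n) < params.p_male, "male", "female")
    trauma = rng.random(n) < params.p_trauma
    attendant = rng.random(n) < params.p_attendant
    source = rng.choice(np.array(SOURCES), size=n, p=np.array(params.source_probs))
    age = np.maximum(18.0, np.round(rng.normal(params.age_mean, params.age_sd, n)))
    days = np.round(
        np.exp(rng.normal(math.log(params.los_median_days), params.los_log_sd, n))
    ).astype(int)
    preop = rng.random(n) < params.p_preop_given_surgical
    phase = np.where(
        medical, "not_applicable", np.where(preop, "preoperative", "postoperative")
    )

    b0 = calibrate_intercept(params)
    eta = (b0
           + params.beta_mews5 * (totals >= 5)
           + params.beta_medical * medical
           + params.beta_hiv * (hiv == "positive"))
    died = rng.random(n) < _sigmoid(eta)
    discharged = rng.random(n) < params.p_discharged_given_alive
    outcome = np.where(
        selfd, "self_discharged",
        np.where(died, "died", np.where(discharged, "discharged", "on_ward")),
    )

    er = {f: rng.random(n) < p for f, p in zip(ER_FLAGS, params.er_doc_probs)}
    vitals = _sample_vitals_batch(totals, bands, rng)
    dbp = np.round(np.clip(0.65 * vitals["sbp"] + rng.normal(0, 8, n),
                           20, vitals["sbp"] - 5))
    spo2 = np.clip(np.round(rng.normal(96.5, 3.5, n)), 50, 100)

    frame = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "service": np.where(medical, "medical", "surgical"),
            "surgical_phase": phase,
            "trauma": trauma,
            "hiv": hiv,
            "source": source,
            "attendant": attendant,
            "days_pre_enrollment": days,
            "sbp": vitals["sbp"].astype(float),
            "dbp": dbp,
            "pulse": vitals["pulse"].astype(float),
            "rr": vitals["rr"].astype(float),
            "temp": vitals["temp"].astype(float),
            "avpu": vitals["avpu"].astype(str),
            "spo2": spo2,
            "outcome7": outcome,
        }
    )
    for f in ER_FLAGS:
        frame[f"er_{f}_doc"] = er[f]
    return frame


# ---------------------------------------------------------------------------
# published-margin reconstruction (desk-scale fixture)
# ---------------------------------------------------------------------------


def reference_cohort(bands: Optional[ScoreBands] = None) -> pd.DataFrame:
    """Synthetic reconstruction of the study cohort's published margins.

    452 patients whose cutoff-vs-mortality 2x2 tables are exactly the
    published ones (cutoff 4: tp 14, fp 82, fn 11, tn 345; cutoff 5: tp 12,
    fp 41, fn 13, tn 386), and whose univariable risk-factor margins
    (service, sex, trauma, HIV status, discharge disposition) reproduce the
    published unadjusted odds ratios.  Quantities the study did not publish
    — exact MEWS totals within the <4 and >=5 strata, and all joint
    distributions between covariates — are an arbitrary deterministic fill;
    vitals are drawn from a fixed-seed inverse sampler so each row re-scores
    to its assigned total.  Deterministic: no free randomness.
    """
    bands = bands or default_bands()
    dead_totals = ([5] * 6 + [6] * 3 + [7] * 2 + [9]        # 12 at MEWS >= 5
                   + [4] * 2                                 # 2 at MEWS = 4
                   + [3] * 3 + [2] * 3 + [1] * 3 + [0] * 2)  # 11 below 4
    alive_totals = ([5] * 28 + [6] * 9 + [7] * 3 + [8]       # 41 at MEWS >= 5
                    + [4] * 41                               # 41 at MEWS = 4
                    + [0] * 53 + [1] * 96 + [2] * 105 + [3] * 91)  # 345 below 4
    assert len(dead_totals) == 25 and len(alive_totals) == 427

    # deaths: 22 medical / 3 surgical; 13 HIV+ / 7 HIV- / 5 unknown;
    # 3 trauma; 11 female.  survivors carry the complementary margins.
    # within each outcome block the covariates are shuffled with a fixed
    # seed: the margins (hence every published univariable OR) are exact
    # while the unpublished joints stay non-degenerate.
    rng = np.random.default_rng(0)  # fixed: the fixture is deterministic

    def _mix(values: list) -> np.ndarray:
        return rng.permutation(np.array(values, dtype=object))

    dead = pd.DataFrame({
        "mews_total": dead_totals,
        "service": _mix(["medical"] * 22 + ["surgical"] * 3),
        "hiv": _mix(["positive"] * 13 + ["negative"] * 7 + ["unknown"] * 5),
        "trauma": _mix([True] * 3 + [False] * 22).astype(bool),
        "sex": _mix(["female"] * 11 + ["male"] * 14),
        "outcome7": ["died"] * 25,
    })
    alive = pd.DataFrame({
        "mews_total": alive_totals,
        "service": _mix(["medical"] * 182 + ["surgical"] * 245),
        "hiv": _mix(["positive"] * 97 + ["negative"] * 221 + ["unknown"] * 109),
        "trauma": _mix([True] * 82 + [False] * 345).astype(bool),
        "sex": _mix(["female"] * 200 + ["male"] * 227),
        "outcome7": _mix(["discharged"] * 187 + ["on_ward"] * 240),
    })
    frame = pd.concat([dead, alive], ignore_index=True)
    n = len(frame)

    # unpublished fields: plausible deterministic fill
    frame.insert(0, "id", [f"R{i + 1:04d}" for i in range(n)])
    surgical_idx = np.flatnonzero((frame["service"] == "surgical").to_numpy())
    phase = np.array(["not_applicable"] * n, dtype=object)
    phase[surgical_idx[:118]] = "preoperative"
    phase[surgical_idx[118:]] = "postoperative"
    frame["surgical_phase"] = phase
    frame["age"] = 40.0
    frame["attendant"] = np.arange(n) % 452 < 404
    frame["source"] = np.array(SOURCES, dtype=object)[np.arange(n) % 3]
    frame["days_pre_enrollment"] = 9
    for f in ER_FLAGS:
        frame[f"er_{f}_doc"] = False

    vitals = _sample_vitals_batch(frame["mews_total"].to_numpy(), bands, rng)
    for key in ("sbp", "pulse", "rr", "temp"):
        frame[key] = vitals[key].astype(float)
    frame["avpu"] = vitals["avpu"].astype(str)
    frame["dbp"] = np.nan
    frame["spo2"] = np.nan
    frame["mews_critical_ge4"] = frame["mews_total"] >= 4
    frame["mews_critical_ge5"] = frame["mews_total"] >= 5
    return frame
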