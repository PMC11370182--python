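"""Synthetic EHR cohort generator calibrated to the study population.

Emulates a large urban academic-health-system adult cohort (2017–2019):
mean age 62.4 (SD 15.4) truncated to 18–90, 51.3% female, 81.4% Maryland
residents, the published race/ethnicity mix, Poisson utilisation counts and
a mean Charlson comorbidity index of 2.17.

Disease biology is not simulated.  Instead each patient is assigned a latent
*evidence class* — which of the three data types (diagnosis, medication,
laboratory) carry type-2-diabetes-qualifying patterns for them, or none.
A class member type receives patterns strong enough to satisfy the
strictest shipped criterion for that type (two diagnosis events on distinct
days inside a 730-day span; two elevated HbA1c results on distinct days;
at least one antidiabetic dispensing), so the data-type strata of every
definition are populated by construction and set-level assertions are exact.
Background (non-qualifying) events are layered on for all patients.

Everything is a pure function of (profile, seed): identical inputs yield
byte-identical cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import charlson
from .ehr_model import (
    DX, RX, LAB, CODE_SYSTEM_FOR, DEFAULT_STUDY_WINDOW,
    Cohort, ConfigError, PATIENT_COLUMNS, EVENT_COLUMNS,
)

__all__ = [
    "CohortProfile", "default_profile", "generate_patients",
    "assign_evidence_classes", "generate_events", "generate_comorbidities",
    "generate_cohort", "EVIDENCE_CLASSES",
]

#: The 7 non-empty data-type combinations plus "none".
EVIDENCE_CLASSES = ("DX", "RX", "LAB", "DX+RX", "DX+LAB", "RX+LAB",
                    "DX+RX+LAB", "none")

STUDY_START_YEAR = 2017

_QUALIFYING_DX = ("E11.9", "E11.65", "E11.8", "E11.0")
_QUALIFYING_RX = ("6809", "4821", "25789", "593411", "1373458", "475968",
                  "274783", "5856")
_HBA1C = "55454-3"

_BACKGROUND_DX = ("I10", "K21.9", "M54.5", "J06.9", "Z00.00", "F41.9",
                  "N39.0", "H52.4", "M25.50", "R51.9")
_BACKGROUND_RX = ("29046", "83367", "17767", "7646", "10582", "36567",
                  "4493", "32968")

#: Per-category base prevalences for the comorbidity generator; a global
#: multiplier is calibrated so the expected Charlson mean equals the profile
#: target.  Type-1 (E10.x) representative codes are used for the diabetes
#: categories so comorbidity events never intersect the T2D qualifying set.
_CHARLSON_BASE = {
    "myocardial_infarction":          (0.07, "I21.9"),
    "congestive_heart_failure":       (0.13, "I50.9"),
    "peripheral_vascular_disease":    (0.10, "I73.9"),
    "cerebrovascular_disease":        (0.10, "I63.9"),
    "dementia":                       (0.05, "F03.90"),
    "chronic_pulmonary_disease":      (0.17, "J44.9"),
    "rheumatologic_disease":          (0.04, "M06.9"),
    "peptic_ulcer_disease":           (0.02, "K27.9"),
    "mild_liver_disease":             (0.06, "K74.60"),
    "diabetes_uncomplicated":         (0.30, "E10.9"),
    "diabetes_complicated":           (0.12, "E10.21"),
    "hemiplegia_paraplegia":          (0.02, "G81.90"),
    "renal_disease":                  (0.12, "N18.3"),
    "malignancy":                     (0.10, "C50.9"),
    "moderate_severe_liver_disease":  (0.015, "K72.90"),
    "metastatic_solid_tumor":         (0.025, "C78.7"),
    "aids_hiv":                       (0.005, "B20"),
}


def _freeze(d: dict) -> tuple:
    return tuple(sorted(d.items()))


def _thaw(t: tuple) -> dict:
    return dict(t)


@dataclass(frozen=True)
class CohortProfile:
    """All knobs of the generator; defaults reproduce the study population."""

    n_patients: int = 207_813
    age_mean: float = 62.4
    age_sd: float = 15.4
    age_min: int = 18
    age_max: int = 90
    sex_probs: tuple = _freeze({"female": 0.513, "male": 0.486, "other": 0.001})
    race_probs: tuple = _freeze({"white": 0.528, "black": 0.318,
                                 "asian": 0.056, "other": 0.098})
    ethnicity_probs: tuple = _freeze({"non_hispanic": 0.899, "hispanic": 0.053,
                                      "other": 0.048})
    p_maryland: float = 0.814
    inpatient_visit_mean: float = 0.657
    ed_visit_mean: float = 1.01
    cci_mean: float = 2.17
    #: ~78% of patients carry some qualifying evidence; every non-empty
    #: combination has probability >= 0.05 so all strata are populated.
    evidence_class_probs: tuple = _freeze({
        "DX": 0.14, "RX": 0.06, "LAB": 0.06, "DX+RX": 0.17,
        "DX+LAB": 0.12, "RX+LAB": 0.05, "DX+RX+LAB": 0.18, "none": 0.22,
    })
    #: Background (non-qualifying) event rates per patient-year.
    background_rates: tuple = _freeze({DX: 5.0, RX: 3.0, LAB: 4.0})
    charlson_prevalence: tuple = _freeze(
        {k: p for k, (p, _) in _CHARLSON_BASE.items()})
    study_window: tuple = DEFAULT_STUDY_WINDOW

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("sex_probs", "race_probs", "ethnicity_probs",
                     "evidence_class_probs"):
            probs = _thaw(getattr(self, name))
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} has a negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for p in (self.p_maryland,):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("p_maryland must be a probability")


def default_profile(n_patients: int = 207_813) -> CohortProfile:
    """The study-calibrated profile, optionally at a different cohort size."""
    return CohortProfile(n_patients=n_patients)


@lru_cache(maxsize=8)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple:
    """Underlying normal (mu, sigma) whose [lo, hi] truncation has the
    requested mean and SD.

    Naive truncation of N(mean, sd) shifts the realised mean (here by about
    -1.2 years), so the parameters are moment-matched numerically instead.
    """

    def objective(params):
        mu, sig = params
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    (mu, sig), info, ier, msg = optimize.fsolve(
        objective, x0=[mean + 1.5, sd * 1.2], full_output=True)
    if ier != 1:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return float(mu), float(sig)


def _choice(rng, values, probs_tuple, n):
    probs = _thaw(probs_tuple)
    keys = list(probs)
    return rng.choice(keys, size=n, p=[probs[k] for k in keys])


def generate_patients(profile: CohortProfile, seed: int) -> pd.DataFrame:
    """Demographics table; same (profile, seed) gives an identical table."""
    rng = np.random.default_rng(seed)
    n = profile.n_patients
    mu, sig = _truncnorm_params(profile.age_mean, profile.age_sd,
                                profile.age_min - 0.5, profile.age_max + 0.5)
    a = (profile.age_min - 0.5 - mu) / sig
    b = (profile.age_max + 0.5 - mu) / sig
    ages = stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)
    ages = np.clip(np.round(ages).astype(int), profile.age_min, profile.age_max)

    patients = pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "birth_year": STUDY_START_YEAR - ages,
        "sex": _choice(rng, None, profile.sex_probs, n),
        "race": _choice(rng, None, profile.race_probs, n),
        "ethnicity": _choice(rng, None, profile.ethnicity_probs, n),
        "state": np.where(rng.random(n) < profile.p_maryland, "MD", "other"),
        "inpatient_visits": rng.poisson(profile.inpatient_visit_mean, n),
        "ed_visits": rng.poisson(profile.ed_visit_mean, n),
    })
    return patients[PATIENT_COLUMNS]


def assign_evidence_classes(patients: pd.DataFrame, profile: CohortProfile,
                            seed: int) -> pd.Series:
    """Latent class per patient; deterministic sub-step of generate_events."""
    rng = np.random.default_rng([seed, 101])
    classes = _choice(rng, None, profile.evidence_class_probs, len(patients))
    return pd.Series(classes, index=patients["patient_id"].to_numpy(),
                     name="evidence_class")


def _window_days(window: tuple) -> int:
    return (window[1] - window[0]).days + 1


def _dates_from_offsets(start: date, offsets: np.ndarray) -> np.ndarray:
    return (np.datetime64(start) + offsets.astype("timedelta64[D]")
            ).astype("datetime64[ns]")


def _qualifying_pair_offsets(rng, n: int, span: int) -> tuple:
    """Two distinct day offsets per patient inside [0, span)."""
    first = rng.integers(0, span, n)
    second = (first + 1 + rng.integers(0, span - 1, n)) % span
    return first, second


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": pd.Series(dtype=str),
        "data_type": pd.Series(dtype=str),
        "code_system": pd.Series(dtype=str),
        "code": pd.Series(dtype=str),
        "event_date": pd.Series(dtype="datetime64[ns]"),
        "setting": pd.Series(dtype=str),
        "value": pd.Series(dtype=float),
        "unit": pd.Series(dtype=str),
    })


def _frame(patient_id, data_type, code, event_date, setting="", value=np.nan,
           unit=""):
    n = len(patient_id)
    return pd.DataFrame({
        "patient_id": np.asarray(patient_id, dtype=object),
        "data_type": np.repeat(data_type, n),
        "code_system": np.repeat(CODE_SYSTEM_FOR[data_type], n),
        "code": np.asarray(code, dtype=object),
        "event_date": event_date,
        "setting": setting if not np.isscalar(setting) else np.repeat(setting, n),
        "value": value if not np.isscalar(value) else np.repeat(float(value), n),
        "unit": unit if not np.isscalar(unit) else np.repeat(unit, n),
    })


def generate_events(patients: pd.DataFrame, profile: CohortProfile,
                    seed: int) -> pd.DataFrame:
    """Qualifying + background clinical events for every patient.

    Qualifying patterns are drawn inside the trailing 730 days of the study
    window (the tightest shipped reference period), so a class member type
    satisfies every shipped criterion for that type.  Background events are
    spread over the whole window, never match a T2D code set with a
    qualifying value, and include normal-range HbA1c results (clustered
    around 5.4–5.8%).
    """
    if not len(patients):
        raise ConfigError("patients table is empty")
    classes = assign_evidence_classes(patients, profile, seed)
    rng = np.random.default_rng([seed, 202])
    window = profile.study_window
    total_days = _window_days(window)
    ref_days = min(730, total_days)
    ref_start = window[1] - timedelta(days=ref_days - 1)
    pids = patients["patient_id"].to_numpy()
    frames = []

    has = {t: classes.str.contains(t).to_numpy() for t in (DX, RX, LAB)}

    # --- qualifying diagnosis: two distinct days within the 730-day span
    ids = pids[has[DX]]
    if len(ids):
        o1, o2 = _qualifying_pair_offsets(rng, len(ids), ref_days)
        extra = rng.poisson(1.0, len(ids))
        rep_ids = np.concatenate([ids, ids, np.repeat(ids, extra)])
        offs = np.concatenate([o1, o2, rng.integers(0, ref_days, extra.sum())])
        codes = rng.choice(_QUALIFYING_DX, len(rep_ids))
        settings = rng.choice(["outpatient", "inpatient", "ed"],
                              size=len(rep_ids), p=[0.80, 0.15, 0.05])
        frames.append(_frame(rep_ids, DX, codes,
                             _dates_from_offsets(ref_start, offs), settings))

    # --- qualifying medication: two dispensings on distinct days
    ids = pids[has[RX]]
    if len(ids):
        o1, o2 = _qualifying_pair_offsets(rng, len(ids), ref_days)
        extra = rng.poisson(0.7, len(ids))
        rep_ids = np.concatenate([ids, ids, np.repeat(ids, extra)])
        offs = np.concatenate([o1, o2, rng.integers(0, ref_days, extra.sum())])
        codes = rng.choice(_QUALIFYING_RX, len(rep_ids))
        frames.append(_frame(rep_ids, RX, codes,
                             _dates_from_offsets(ref_start, offs)))

    # --- qualifying laboratory: two elevated HbA1c on distinct days
    ids = pids[has[LAB]]
    if len(ids):
        o1, o2 = _qualifying_pair_offsets(rng, len(ids), ref_days)
        extra = rng.poisson(0.5, len(ids))
        rep_ids = np.concatenate([ids, ids, np.repeat(ids, extra)])
        offs = np.concatenate([o1, o2, rng.integers(0, ref_days, extra.sum())])
        vals = np.clip(rng.normal(8.3, 1.4, len(rep_ids)), 6.6, 13.5)
        frames.append(_frame(rep_ids, LAB, np.repeat(_HBA1C, len(rep_ids)),
                             _dates_from_offsets(ref_start, offs),
                             value=np.round(vals, 1), unit="%"))

    # --- background noise, all patients, whole window
    rates = _thaw(profile.background_rates)
    years = total_days / 365.25
    n = len(pids)

    k = rng.poisson(rates[DX] * years, n)
    rep_ids = np.repeat(pids, k)
    m = len(rep_ids)
    if m:
        frames.append(_frame(
            rep_ids, DX, rng.choice(_BACKGROUND_DX, m),
            _dates_from_offsets(window[0], rng.integers(0, total_days, m)),
            rng.choice(["outpatient", "inpatient", "ed"], size=m,
                       p=[0.85, 0.10, 0.05])))

    k = rng.poisson(rates[RX] * years, n)
    rep_ids = np.repeat(pids, k)
    m = len(rep_ids)
    if m:
        frames.append(_frame(
            rep_ids, RX, rng.choice(_BACKGROUND_RX, m),
            _dates_from_offsets(window[0], rng.integers(0, total_days, m))))

    k = rng.poisson(rates[LAB] * years, n)
    rep_ids = np.repeat(pids, k)
    m = len(rep_ids)
    if m:
        analyte = rng.choice(4, m, p=[0.35, 0.30, 0.15, 0.20])
        codes = np.array(["55454-3", "2345-7", "1558-6", "2093-3"])[analyte]
        units = np.array(["%", "mg/dL", "mg/dL", "mg/dL"])[analyte]
        vals = np.empty(m)
        vals[analyte == 0] = np.clip(
            rng.normal(5.55, 0.35, (analyte == 0).sum()), 4.8, 6.4)
        vals[analyte == 1] = np.clip(
            rng.normal(95, 18, (analyte == 1).sum()), 60, 199)
        vals[analyte == 2] = np.clip(
            rng.normal(90, 10, (analyte == 2).sum()), 60, 125)
        vals[analyte == 3] = np.clip(
            rng.normal(190, 35, (analyte == 3).sum()), 100, 320)
        frames.append(_frame(
            rep_ids, LAB, codes,
            _dates_from_offsets(window[0], rng.integers(0, total_days, m)),
            value=np.round(vals, 1), unit=units))

    if not frames:
        return _empty_events()
    events = pd.concat(frames, ignore_index=True)
    return events[EVENT_COLUMNS]


def _charlson_multiplier(prevalence: dict, target: float, cmap) -> float:
    """Global factor m with sum(min(m*p, 1) * w) == target (bisection)."""
    weights = {c.name: c.weight for c in cmap}
    missing = set(prevalence) - set(weights)
    if missing:
        raise ConfigError(f"unknown Charlson categories: {sorted(missing)}")

    def expected(m):
        return sum(min(m * p, 1.0) * weights[k] for k, p in prevalence.items())

    hi = 1.0
    while expected(hi) < target:
        hi *= 2
        if hi > 64:
            raise ConfigError("Charlson target unreachable at any prevalence")
    lo = 0.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_comorbidities(patients: pd.DataFrame, profile: CohortProfile,
                           seed: int) -> pd.DataFrame:
    """Charlson-category diagnosis events calibrated to the target mean.

    Categories are independent Bernoulli draws per patient; one representative
    diagnosis event is emitted per present category, dated uniformly inside
    the study window.  A single prevalence multiplier is solved so the
    expected mean index equals ``profile.cci_mean``.
    """
    if not len(patients):
        raise ConfigError("patients table is empty")
    cmap = charlson.load_default_map()
    prevalence = _thaw(profile.charlson_prevalence)
    m = _charlson_multiplier(prevalence, profile.cci_mean, cmap)
    rng = np.random.default_rng([seed, 303])
    window = profile.study_window
    total_days = _window_days(window)
    pids = patients["patient_id"].to_numpy()
    n = len(pids)
    frames = []
    for cat in sorted(prevalence):
        p = min(m * prevalence[cat], 1.0)
        hit = rng.random(n) < p
        ids = pids[hit]
        if not len(ids):
            continue
        code = _CHARLSON_BASE[cat][1]
        offs = rng.integers(0, total_days, len(ids))
        settings = rng.choice(["outpatient", "inpatient"], size=len(ids),
                              p=[0.8, 0.2])
        frames.append(_frame(ids, DX, np.repeat(code, len(ids)),
                             _dates_from_offsets(window[0], offs), settings))
    if not frames:
        return _empty_events()
    return pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]


def generate_cohort(profile: CohortProfile, seed: int) -> Cohort:
    """Full cohort: demographics + clinical events + comorbidity events."""
    patients = generate_patients(profile, seed)
    events = pd.concat([
        generate_events(patients, profile, seed),
        generate_comorbidities(patients, profile, seed),
    ], ignore_index=True)
    events = events.sort_values(
        ["patient_id", "event_date", "data_type", "code"],
        kind="mergesort").reset_index(drop=True)
    events["event_id"] = np.arange(len(events), dtype=np.int64)
    return Cohort(patients, events, profile.study_window)
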