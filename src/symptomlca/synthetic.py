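"""Synthetic cohorts from a known latent-class truth.

The study data this package is designed for (symptom surveys of young
women linked to administrative service-use records) are
access-restricted, so every downstream stage is exercised on synthetic
cohorts generated from a fully specified truth: latent classes drawn
from known prevalences, 19 raw four-level symptom responses drawn
class-conditionally (independent given class), class-conditional
categorical covariates, class-conditional service-use outcomes
rendered as dated visit/dispensing/admission records (with decoy
records outside the counting windows to exercise the filters), and
item-level MCAR missingness.

``implied_rho`` converts the four-level generative truth into the
exact three-level item-response probabilities of the 16 analysis
indicators (closed form, by enumeration over the source-item joint),
which is what parameter-recovery tests compare fitted models against.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recode import (
    BOWEL_ITEMS,
    GP_BINS,
    INDICATORS,
    MEDICATION_BINS,
    RAW_ITEMS,
    RESPONSE_LABELS,
    SPECIALIST_BINS,
    URINARY_ITEMS,
    collapse_to_three,
    combine_any_symptom,
)

__all__ = ["SyntheticSpec", "Cohort", "generate_cohort", "implied_rho", "scenario_library"]

#: count ranges used to realise a sampled outcome bin as an actual count
GP_BIN_RANGES = [(0, 1), (2, 3), (4, 6), (7, 9), (10, 12), (13, 16)]
SPECIALIST_BIN_RANGES = [(0, 0), (1, 2), (3, 5)]
MEDICATION_BIN_RANGES = [(0, 0), (1, 1), (2, 2), (3, 5)]

_ATC_POOL = [
    "A01AA01", "A02BC01", "A10BA02", "B01AC06", "C07AB02", "C09AA02", "C10AA01",
    "D01AC02", "G03AA07", "G03AC09", "H03AA01", "J01CA04", "J01FA09", "L04AX03",
    "M01AE01", "N02BE01", "N02CC01", "N05AH04", "N06AB06", "N06AX16", "R03AC02",
    "R06AE07", "S01AA01", "V03AB15",
]
_ICD_POOL = ["K35.8", "J18.9", "S52.5", "N10", "K80.2", "M54.5", "F32.1", "E66.9"]
_PREGNANCY_CODE = "O80"

BASE_RETURN_DATE = _dt.date(2017, 2, 1)  # survey returns spread over ~90 days from here


@dataclass
class SyntheticSpec:
    """Complete generative description of a synthetic cohort."""

    n: int
    C: int
    gamma: np.ndarray  # (C,)
    raw_response_model: np.ndarray  # (C, 19, 4) class-conditional response probs
    covariate_model: dict = field(default_factory=dict)  # name -> levels + probs
    gp_model: np.ndarray | None = None  # (C, 6)
    specialist_model: np.ndarray | None = None  # (C, 3)
    medication_model: np.ndarray | None = None  # (C, 4)
    admission_model: np.ndarray | None = None  # (C, 2): P(same-day), P(overnight)
    missing_rate: float = 0.02
    seed: int = 0
    name: str = "custom"

    def validate(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if np.any(g < 0) or abs(g.sum() - 1) > 1e-8:
            raise ValueError("gamma is not on the simplex")
        r = np.asarray(self.raw_response_model, dtype=float)
        if r.shape != (self.C, len(RAW_ITEMS), 4):
            raise ValueError(f"raw_response_model must have shape ({self.C}, 19, 4)")
        if np.any(r < 0) or not np.allclose(r.sum(axis=2), 1.0, atol=1e-8):
            raise ValueError("raw response distributions are not on the simplex")
        for m, k in [
            (self.gp_model, 6),
            (self.specialist_model, 3),
            (self.medication_model, 4),
        ]:
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != (self.C, k) or np.any(m < 0) or not np.allclose(
                    m.sum(axis=1), 1.0, atol=1e-8
                ):
                    raise ValueError("outcome model distributions are not on the simplex")
        for name, cv in self.covariate_model.items():
            p = np.asarray(cv["probs"], dtype=float)
            if np.any(p < 0) or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
                raise ValueError(f"covariate model for {name!r} is not on the simplex")


@dataclass
class Cohort:
    """A generated cohort; truth labels are kept separate from pipeline inputs."""

    survey: pd.DataFrame
    covariates: pd.DataFrame
    visits: pd.DataFrame
    dispensings: pd.DataFrame
    admissions: pd.DataFrame
    survey_dates: pd.Series
    outcome_categories: pd.DataFrame  # sampled bins, for evaluation shortcuts
    truth: pd.Series  # true class labels — evaluation only
    spec: SyntheticSpec


def _sample_categorical(rng, probs, size):
    """Vectorised draw from one categorical distribution."""
    return rng.choice(len(probs), size=size, p=probs)


def generate_cohort(
    spec: SyntheticSpec, seed: int | None = None, render_records: bool = True
) -> Cohort:
    """Draw a full cohort from the spec.

    ``seed`` overrides ``spec.seed``; with equal seeds the cohort is
    identical draw for draw.  When ``render_records`` is false the
    dated service-record tables are left empty and only the sampled
    outcome categories are returned (cheap path for simulation loops
    that do not exercise the record-level recode).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, C = spec.n, spec.C
    z = rng.choice(C, size=n, p=np.asarray(spec.gamma, dtype=float))

    # Raw symptom responses, class-conditional, then MCAR mask.
    raw = np.empty((n, len(RAW_ITEMS)), dtype=np.int64)
    rrm = np.asarray(spec.raw_response_model, dtype=float)
    for c in range(C):
        mask = z == c
        for j in range(len(RAW_ITEMS)):
            raw[mask, j] = _sample_categorical(rng, rrm[c, j], mask.sum())
    if spec.missing_rate > 0:
        miss = rng.random(raw.shape) < spec.missing_rate
        raw = np.where(miss, -1, raw)
    survey = pd.DataFrame(
        {item: [RESPONSE_LABELS.get(v, np.nan) for v in raw[:, j]]
         for j, item in enumerate(RAW_ITEMS)}
    )
    pids = np.arange(1, n + 1)
    survey.insert(0, "participant_id", pids)

    # Covariates.
    cov = {"participant_id": pids}
    for name, cv in spec.covariate_model.items():
        levels = list(cv["levels"])
        probs = np.asarray(cv["probs"], dtype=float)
        codes = np.empty(n, dtype=np.int64)
        if probs.ndim == 1:  # class-independent
            codes[:] = _sample_categorical(rng, probs, n)
        else:
            for c in range(C):
                mask = z == c
                codes[mask] = _sample_categorical(rng, probs[c], mask.sum())
        cov[name] = pd.Categorical.from_codes(codes, categories=levels)
    covariates = pd.DataFrame(cov)

    return_dates = pd.Series(
        [BASE_RETURN_DATE + _dt.timedelta(days=int(d)) for d in rng.integers(0, 90, n)],
        index=pd.Index(pids, name="participant_id"),
        name="survey_return_date",
    )

    # Outcome bins per individual (the truth the distal analysis estimates).
    def _bins(model, labels):
        if model is None:
            return pd.Categorical([labels[0]] * n, categories=labels)
        model = np.asarray(model, dtype=float)
        codes = np.empty(n, dtype=np.int64)
        for c in range(C):
            mask = z == c
            codes[mask] = _sample_categorical(rng, model[c], mask.sum())
        return pd.Categorical.from_codes(codes, categories=labels)

    gp_cat = _bins(spec.gp_model, GP_BINS)
    sp_cat = _bins(spec.specialist_model, SPECIALIST_BINS)
    med_cat = _bins(spec.medication_model, MEDICATION_BINS)
    if spec.admission_model is not None:
        adm = np.asarray(spec.admission_model, dtype=float)
        p_sd, p_on = adm[z, 0], adm[z, 1]
        same_day = rng.random(n) < p_sd
        overnight = rng.random(n) < p_on
    else:
        same_day = np.zeros(n, dtype=bool)
        overnight = np.zeros(n, dtype=bool)
    outcome_categories = pd.DataFrame(
        {
            "gp_category": gp_cat,
            "specialist_category": sp_cat,
            "medication_category": med_cat,
            "any_admission": same_day | overnight,
            "same_day_admission": same_day,
            "overnight_admission": overnight,
        },
        index=pd.Index(pids, name="participant_id"),
    )

    visits_rows, disp_rows, adm_rows = [], [], []
    if render_records:
        year = BASE_RETURN_DATE.year
        med_lo = _dt.date(year, 4, 1)
        med_days = (_dt.date(year, 9, 30) - med_lo).days + 1
        for i, pid in enumerate(pids):
            ret = return_dates.iloc[i]
            gp_n = int(rng.integers(*np.array(GP_BIN_RANGES[gp_cat.codes[i]]) + (0, 1)))
            sp_n = int(rng.integers(*np.array(SPECIALIST_BIN_RANGES[sp_cat.codes[i]]) + (0, 1)))
            for _ in range(gp_n):
                d = ret + _dt.timedelta(days=int(rng.integers(0, 365)))
                visits_rows.append((pid, d, "gp"))
            for _ in range(sp_n):
                d = ret + _dt.timedelta(days=int(rng.integers(0, 365)))
                visits_rows.append((pid, d, "specialist"))
            if rng.random() < 0.3:  # decoy visit after the 12-month window
                visits_rows.append((pid, ret + _dt.timedelta(days=int(rng.integers(365, 420))), "gp"))
            med_n = int(rng.integers(*np.array(MEDICATION_BIN_RANGES[med_cat.codes[i]]) + (0, 1)))
            codes = rng.choice(len(_ATC_POOL), size=med_n, replace=False)
            for k in codes:
                d = med_lo + _dt.timedelta(days=int(rng.integers(0, med_days)))
                disp_rows.append((pid, _ATC_POOL[k], d))
                if rng.random() < 0.2:  # repeat dispensing of the same substance
                    d2 = med_lo + _dt.timedelta(days=int(rng.integers(0, med_days)))
                    disp_rows.append((pid, _ATC_POOL[k], d2))
            if rng.random() < 0.2:  # decoy dispensing after the Apr-Sep window
                k = int(rng.integers(0, len(_ATC_POOL)))
                disp_rows.append((pid, _ATC_POOL[k], _dt.date(year, 10, int(rng.integers(1, 29)))))
            if same_day[i]:
                d = ret + _dt.timedelta(days=int(rng.integers(0, 365)))
                adm_rows.append((pid, d, True, _ICD_POOL[int(rng.integers(0, len(_ICD_POOL)))]))
            if overnight[i]:
                d = ret + _dt.timedelta(days=int(rng.integers(0, 365)))
                adm_rows.append((pid, d, False, _ICD_POOL[int(rng.integers(0, len(_ICD_POOL)))]))
            if rng.random() < 0.05:  # decoy pregnancy-coded admission (excluded by recode)
                d = ret + _dt.timedelta(days=int(rng.integers(0, 365)))
                adm_rows.append((pid, d, bool(rng.random() < 0.5), _PREGNANCY_CODE))

    visits = pd.DataFrame(visits_rows, columns=["participant_id", "date", "provider"])
    dispensings = pd.DataFrame(disp_rows, columns=["participant_id", "atc5", "date"])
    admissions = pd.DataFrame(adm_rows, columns=["participant_id", "date", "same_day", "primary_icd10"])

    truth = pd.Series(z, index=pd.Index(pids, name="participant_id"), name="true_class")
    return Cohort(
        survey=survey,
        covariates=covariates,
        visits=visits,
        dispensings=dispensings,
        admissions=admissions,
        survey_dates=return_dates,
        outcome_categories=outcome_categories,
        truth=truth,
        spec=spec,
    )


def _combine_dist(dists: list[np.ndarray]) -> np.ndarray:
    """Exact 4-level distribution of the "any symptom" combination.

    Enumerates the joint of the (class-conditionally independent)
    source items and pushes each cell through the priority rule.
    """
    out = np.zeros(4)
    for combo in itertools.product(range(4), repeat=len(dists)):
        p = 1.0
        for d, v in zip(dists, combo):
            p *= d[v]
        out[combine_any_symptom(list(combo))] += p
    return out


def implied_rho(spec: SyntheticSpec) -> np.ndarray:
    """Exact (C, 16, 3) indicator-response probabilities implied by the raw model."""
    rrm = np.asarray(spec.raw_response_model, dtype=float)
    C = spec.C
    rho = np.zeros((C, len(INDICATORS), 3))
    collapse = np.zeros((4, 3))
    for v in range(4):
        collapse[v, collapse_to_three(v)] = 1.0
    uri_idx = [RAW_ITEMS.index(i) for i in URINARY_ITEMS]
    bow_idx = [RAW_ITEMS.index(i) for i in BOWEL_ITEMS]
    for c in range(C):
        for jj, ind in enumerate(INDICATORS):
            if ind == "any_urinary":
                d4 = _combine_dist([rrm[c, j] for j in uri_idx])
            elif ind == "any_bowel":
                d4 = _combine_dist([rrm[c, j] for j in bow_idx])
            else:
                d4 = rrm[c, RAW_ITEMS.index(ind)]
            rho[c, jj] = d4 @ collapse
    return rho


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

# Four-level response-distribution presets (never, rarely, sometimes, often).
_VERY_LOW = np.array([0.80, 0.14, 0.05, 0.01])
_LOW = np.array([0.58, 0.26, 0.12, 0.04])
_MODERATE = np.array([0.38, 0.26, 0.26, 0.10])
_HIGH_SOME = np.array([0.14, 0.16, 0.48, 0.22])
_HIGH_OFTEN = np.array([0.04, 0.08, 0.33, 0.55])

_MENSTRUAL = ["premenstrual_tension", "heavy_periods", "severe_period_pain"]
_MOOD = ["depression", "intense_anxiety", "palpitations"]


def _raw_model(rows: dict) -> np.ndarray:
    """Assemble a (C, 19, 4) model from {class: {item: dist}} with a default."""
    C = len(rows)
    out = np.zeros((C, len(RAW_ITEMS), 4))
    for c in range(C):
        spec_c = rows[c]
        default = spec_c.get("default", _LOW)
        for j, item in enumerate(RAW_ITEMS):
            out[c, j] = spec_c.get(item, default)
    return out


def _paper_like_raw() -> np.ndarray:
    minimal = {"default": _LOW, "allergies": _MODERATE}
    menstrual = {
        "default": _LOW,
        **{m: _HIGH_OFTEN for m in _MENSTRUAL},
        "irregular_periods": _HIGH_SOME,
        "severe_tiredness": _HIGH_SOME,
        "difficulty_sleeping": _HIGH_SOME,
        **{m: _VERY_LOW for m in _MOOD},
    }
    mood = {
        "default": _MODERATE,
        **{m: _HIGH_OFTEN for m in _MOOD},
        "severe_tiredness": _HIGH_OFTEN,
        "difficulty_sleeping": _HIGH_SOME,
        "headaches_migraines": _HIGH_SOME,
        **{m: _VERY_LOW for m in _MENSTRUAL},
        "irregular_periods": _LOW,
    }
    many = {"default": _HIGH_OFTEN}
    return _raw_model({0: minimal, 1: menstrual, 2: mood, 3: many})


#: service-use gradients: Minimal < Menstrual < Mood < Many
_GP_GRADIENT = np.array(
    [
        [0.42, 0.30, 0.18, 0.06, 0.02, 0.02],
        [0.30, 0.30, 0.24, 0.09, 0.04, 0.03],
        [0.22, 0.28, 0.27, 0.12, 0.06, 0.05],
        [0.10, 0.18, 0.26, 0.18, 0.12, 0.16],
    ]
)
_SPECIALIST_GRADIENT = np.array(
    [[0.70, 0.22, 0.08], [0.58, 0.29, 0.13], [0.50, 0.33, 0.17], [0.38, 0.39, 0.23]]
)
_MEDICATION_GRADIENT = np.array(
    [
        [0.52, 0.22, 0.13, 0.13],
        [0.40, 0.25, 0.15, 0.20],
        [0.32, 0.25, 0.17, 0.26],
        [0.18, 0.20, 0.19, 0.43],
    ]
)
_ADMISSION_GRADIENT = np.array([[0.04, 0.035], [0.06, 0.05], [0.08, 0.06], [0.13, 0.11]])

_COVARIATE_LEVELS = {
    "education": ["degree", "certificate", "high_school"],
    "income_difficulty": ["easy", "sometimes", "always"],
    "smoking": ["no", "yes"],
    "physical_activity": ["active", "inactive"],
}

_COVARIATES_BY_CLASS = {
    "education": {
        "levels": _COVARIATE_LEVELS["education"],
        "probs": np.array(
            [[0.73, 0.16, 0.11], [0.61, 0.26, 0.13], [0.53, 0.29, 0.18], [0.33, 0.41, 0.26]]
        ),
    },
    "income_difficulty": {
        "levels": _COVARIATE_LEVELS["income_difficulty"],
        "probs": np.array(
            [[0.70, 0.24, 0.06], [0.53, 0.36, 0.11], [0.43, 0.37, 0.20], [0.26, 0.37, 0.37]]
        ),
    },
    "smoking": {
        "levels": _COVARIATE_LEVELS["smoking"],
        "probs": np.array([[0.92, 0.08], [0.86, 0.14], [0.83, 0.17], [0.71, 0.29]]),
    },
    "physical_activity": {
        "levels": _COVARIATE_LEVELS["physical_activity"],
        "probs": np.array([[0.77, 0.23], [0.72, 0.28], [0.65, 0.35], [0.59, 0.41]]),
    },
}

_COVARIATES_MARGINAL = {
    name: {"levels": cv["levels"], "probs": np.array([0.55, 0.30, 0.15][: len(cv["levels"])])
           / sum([0.55, 0.30, 0.15][: len(cv["levels"])])}
    for name, cv in _COVARIATES_BY_CLASS.items()
}


def _high_separation_raw() -> np.ndarray:
    """Four classes, each item distribution concentrated (>= 0.8) on one level."""
    never_d = np.array([0.90, 0.05, 0.03, 0.02])
    some_d = np.array([0.04, 0.03, 0.90, 0.03])
    often_d = np.array([0.03, 0.03, 0.04, 0.90])
    C = 4
    out = np.zeros((C, len(RAW_ITEMS), 4))
    for j in range(len(RAW_ITEMS)):
        out[0, j] = never_d
        out[1, j] = some_d if j % 2 == 0 else never_d
        out[2, j] = often_d if j % 2 == 1 else never_d
        out[3, j] = often_d
    return out


def _low_separation_raw() -> np.ndarray:
    """Three heavily overlapping classes (entropy around 0.6-0.75)."""
    base = np.array([0.44, 0.26, 0.20, 0.10])
    up = np.array([0.18, 0.18, 0.36, 0.28])
    dn = np.array([0.68, 0.22, 0.07, 0.03])
    C = 3
    out = np.zeros((C, len(RAW_ITEMS), 4))
    for j in range(len(RAW_ITEMS)):
        out[0, j] = dn if j < 10 else base
        out[1, j] = base if j < 8 else up
        out[2, j] = up if j % 2 == 0 else base
    return out


def scenario_library() -> dict[str, SyntheticSpec]:
    """Named generative scenarios used throughout the test and simulation suites.

    - ``paper_like``: four classes with the study's published
      prevalences (36.6 / 21.9 / 26.2 / 15.3 percent), qualitative
      profiles matching the four named symptom patterns (minimal,
      menstrual-elevated/mood-suppressed, mood-elevated/
      menstrual-suppressed, elevated-everywhere) and a monotone
      service-use gradient across classes.
    - ``high_separation``: concentrated response profiles, entropy > 0.9.
    - ``low_separation``: overlapping profiles, entropy around 0.6-0.75.
    - ``null_covariates``: covariates generated independent of class.
    - ``confounded``: covariates strongly class-dependent (for balance
      diagnostics).
    """
    lib = {}
    lib["paper_like"] = SyntheticSpec(
        n=7797,
        C=4,
        gamma=np.array([0.366, 0.219, 0.262, 0.153]),
        raw_response_model=_paper_like_raw(),
        covariate_model=_COVARIATES_BY_CLASS,
        gp_model=_GP_GRADIENT,
        specialist_model=_SPECIALIST_GRADIENT,
        medication_model=_MEDICATION_GRADIENT,
        admission_model=_ADMISSION_GRADIENT,
        name="paper_like",
    )
    lib["high_separation"] = SyntheticSpec(
        n=5000,
        C=4,
        gamma=np.array([0.30, 0.26, 0.24, 0.20]),
        raw_response_model=_high_separation_raw(),
        covariate_model=_COVARIATES_BY_CLASS,
        gp_model=_GP_GRADIENT,
        specialist_model=_SPECIALIST_GRADIENT,
        medication_model=_MEDICATION_GRADIENT,
        admission_model=_ADMISSION_GRADIENT,
        name="high_separation",
    )
    lib["low_separation"] = SyntheticSpec(
        n=5000,
        C=3,
        gamma=np.array([0.45, 0.30, 0.25]),
        raw_response_model=_low_separation_raw(),
        covariate_model={k: _COVARIATES_BY_CLASS[k] for k in ["smoking"]},
        gp_model=_GP_GRADIENT[:3],
        specialist_model=_SPECIALIST_GRADIENT[:3],
        medication_model=_MEDICATION_GRADIENT[:3],
        admission_model=_ADMISSION_GRADIENT[:3],
        name="low_separation",
    )
    lib["null_covariates"] = SyntheticSpec(
        n=2000,
        C=3,
        gamma=np.array([0.45, 0.30, 0.25]),
        raw_response_model=_high_separation_raw()[:3],
        covariate_model=_COVARIATES_MARGINAL,
        gp_model=_GP_GRADIENT[:3],
        specialist_model=_SPECIALIST_GRADIENT[:3],
        medication_model=_MEDICATION_GRADIENT[:3],
        admission_model=_ADMISSION_GRADIENT[:3],
        name="null_covariates",
    )
    lib["confounded"] = SyntheticSpec(
        n=2000,
        C=4,
        gamma=np.array([0.366, 0.219, 0.262, 0.153]),
        raw_response_model=_high_separation_raw(),
        covariate_model=_COVARIATES_BY_CLASS,
        gp_model=_GP_GRADIENT,
        specialist_model=_SPECIALIST_GRADIENT,
        medication_model=_MEDICATION_GRADIENT,
        admission_model=_ADMISSION_GRADIENT,
        name="confounded",
    )
    return lib
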