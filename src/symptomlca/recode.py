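"""Recoding of raw symptom survey items and linked service records.

The survey asks about 19 symptoms on a four-level frequency scale
(never / rarely / sometimes / often).  The analysis consumes 16
three-category indicators: the two urinary items and the three bowel
items are each combined into an "any" item by a priority rule, and the
never/rarely levels are collapsed.  Linked administrative records
(GP and specialist visits, dispensings, hospital admissions) are
reduced to categorical health-service-use outcomes over fixed windows.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Four-level response codes.  Missing is represented as -1 internally
# and as NaN / blank in DataFrames.
NEVER, RARELY, SOMETIMES, OFTEN, MISSING = 0, 1, 2, 3, -1

RESPONSE_CODES = {"never": NEVER, "rarely": RARELY, "sometimes": SOMETIMES, "often": OFTEN}
RESPONSE_LABELS = {v: k for k, v in RESPONSE_CODES.items()}

#: The 19 raw survey items, in survey order.
RAW_ITEMS = [
    "allergies",
    "headaches_migraines",
    "severe_tiredness",
    "back_pain",
    "vaginal_discharge_irritation",
    "premenstrual_tension",
    "irregular_periods",
    "heavy_periods",
    "severe_period_pain",
    "skin_problems",
    "difficulty_sleeping",
    "depression",
    "intense_anxiety",
    "palpitations",
    "urine_burns",
    "urine_leak",
    "constipation",
    "haemorrhoids",
    "other_bowel",
]

URINARY_ITEMS = ["urine_burns", "urine_leak"]
BOWEL_ITEMS = ["constipation", "haemorrhoids", "other_bowel"]

#: The 16 final indicators: 14 retained single items + the two combined ones.
INDICATORS = [it for it in RAW_ITEMS if it not in URINARY_ITEMS + BOWEL_ITEMS] + [
    "any_urinary",
    "any_bowel",
]

GP_BINS = ["<2 visits", "2-3 visits", "4-6 visits", "7-9 visits", "10-12 visits", ">12 visits"]
SPECIALIST_BINS = ["No visits", "1-2 visits", "3+ visits"]
MEDICATION_BINS = ["no prescriptions", "1 prescription", "2 prescriptions", "3+ prescriptions"]

_ATC5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z](\.?[0-9A-Z]{1,4})?$")


class RecodeError(ValueError):
    """A value outside its declared domain was encountered during recoding."""


def _to_code(value) -> int:
    """Map a raw response (label string, integer code, or NaN) to an internal code."""
    if value is None:
        return MISSING
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("", "na", "nan", "missing"):
            return MISSING
        if v in RESPONSE_CODES:
            return RESPONSE_CODES[v]
        try:
            value = int(v)
        except ValueError:
            raise RecodeError(f"unknown response value {value!r}")
    if isinstance(value, float) and np.isnan(value):
        return MISSING
    iv = int(value)
    if iv == MISSING or 0 <= iv <= 3:
        return iv
    raise RecodeError(f"response code {value!r} outside 0-3")


def combine_any_symptom(responses) -> int:
    """Combine two or three four-level responses into an "any symptom" response.

    Priority rule: if every observed response is 'never' the combined
    response is 'never'; otherwise any 'often' dominates, then any
    'sometimes', and the residual case is 'rarely'.  Missing source
    items are ignored; if all are missing the result is missing.
    """
    codes = [_to_code(r) for r in responses]
    if len(codes) == 0:
        raise RecodeError("combine_any_symptom needs at least one response")
    obs = [c for c in codes if c != MISSING]
    if not obs:
        return MISSING
    if all(c == NEVER for c in obs):
        return NEVER
    if any(c == OFTEN for c in obs):
        return OFTEN
    if any(c == SOMETIMES for c in obs):
        return SOMETIMES
    return RARELY


def collapse_to_three(response) -> int:
    """Collapse a four-level response to the three-level indicator scale.

    never/rarely -> 0, sometimes -> 1, often -> 2; missing propagates.
    """
    c = _to_code(response)
    if c == MISSING:
        return MISSING
    return {NEVER: 0, RARELY: 0, SOMETIMES: 1, OFTEN: 2}[c]


def build_indicator_matrix(survey: pd.DataFrame, id_col: str = "participant_id") -> pd.DataFrame:
    """Build the n x 16 three-category indicator matrix from raw survey rows.

    Parameters
    ----------
    survey : DataFrame with one row per participant, the 19 raw item
        columns (labels or 0-3 codes; NaN/blank = missing) and an
        identifier column.

    Returns
    -------
    DataFrame indexed by participant id with the 16 indicator columns,
    values in {0, 1, 2} or NaN.  Rows missing on all 16 indicators are
    dropped (the count is logged).
    """
    missing_cols = [c for c in RAW_ITEMS if c not in survey.columns]
    if missing_cols:
        raise RecodeError(f"survey is missing raw item columns: {missing_cols}")
    if len(survey) == 0:
        raise RecodeError("empty survey table")

    raw = np.empty((len(survey), len(RAW_ITEMS)), dtype=np.int64)
    for j, item in enumerate(RAW_ITEMS):
        raw[:, j] = [_to_code(v) for v in survey[item]]

    singles = [it for it in RAW_ITEMS if it not in URINARY_ITEMS + BOWEL_ITEMS]
    out = {}
    for item in singles:
        j = RAW_ITEMS.index(item)
        out[item] = [collapse_to_three(v) for v in raw[:, j]]
    uri_idx = [RAW_ITEMS.index(it) for it in URINARY_ITEMS]
    bow_idx = [RAW_ITEMS.index(it) for it in BOWEL_ITEMS]
    out["any_urinary"] = [
        collapse_to_three(combine_any_symptom(raw[i, uri_idx])) for i in range(len(survey))
    ]
    out["any_bowel"] = [
        collapse_to_three(combine_any_symptom(raw[i, bow_idx])) for i in range(len(survey))
    ]

    mat = pd.DataFrame(out, columns=INDICATORS, dtype=float)
    mat = mat.mask(mat < 0)  # MISSING -> NaN
    if id_col in survey.columns:
        mat.index = pd.Index(survey[id_col], name=id_col)
    all_missing = mat.isna().all(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        logger.info("dropped %d rows missing on all %d indicators", n_dropped, len(INDICATORS))
    return mat.loc[~all_missing]


def bin_gp_visits(count: int) -> str:
    """Map a 12-month GP visit count onto the six published bins."""
    if count < 0:
        raise RecodeError("negative visit count")
    if count < 2:
        return GP_BINS[0]
    if count <= 3:
        return GP_BINS[1]
    if count <= 6:
        return GP_BINS[2]
    if count <= 9:
        return GP_BINS[3]
    if count <= 12:
        return GP_BINS[4]
    return GP_BINS[5]


def bin_specialist_visits(count: int) -> str:
    if count < 0:
        raise RecodeError("negative visit count")
    if count == 0:
        return SPECIALIST_BINS[0]
    if count <= 2:
        return SPECIALIST_BINS[1]
    return SPECIALIST_BINS[2]


def bin_medications(count: int) -> str:
    if count < 0:
        raise RecodeError("negative medication count")
    if count >= 3:
        return MEDICATION_BINS[3]
    return MEDICATION_BINS[count]


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return pd.Timestamp(d).date()


def is_pregnancy_code(icd10: str) -> bool:
    """True when the primary ICD-10 category falls in O00-O9A (pregnancy-related).

    The comparison is on the three-character category prefix with the
    ICD-10 ordering in which digits precede letters in the third
    position, so O9A is the inclusive upper bound.
    """
    code = icd10.strip().upper()
    if not _ICD10_RE.match(code):
        raise RecodeError(f"unparseable ICD-10 code {icd10!r}")
    cat = code[:3]
    if cat[0] != "O" or not cat[1].isdigit():
        return False
    return cat[1] != "9" or cat[2] in "0123456789A"


@dataclass
class ServiceUseRecord:
    """Linked administrative records for one participant."""

    participant_id: object
    survey_return_date: _dt.date
    gp_visit_dates: list = field(default_factory=list)
    specialist_visit_dates: list = field(default_factory=list)
    dispensings: list = field(default_factory=list)  # (atc5, date)
    admissions: list = field(default_factory=list)  # (date, same_day, primary_icd10)


@dataclass
class OutcomeSet:
    gp_category: str
    specialist_category: str
    medication_category: str
    any_admission: bool
    same_day_admission: bool
    overnight_admission: bool


def _in_window(date, start: _dt.date, days: int = 365) -> bool:
    d = _as_date(date)
    return start <= d < start + _dt.timedelta(days=days)


def bin_service_counts(record: ServiceUseRecord) -> tuple[str, str]:
    """GP and specialist categories over the 12 months after survey return.

    The window is half-open: [return date, return date + 365 days).
    """
    start = _as_date(record.survey_return_date)
    gp = sum(_in_window(d, start) for d in record.gp_visit_dates)
    sp = sum(_in_window(d, start) for d in record.specialist_visit_dates)
    return bin_gp_visits(gp), bin_specialist_visits(sp)


def count_unique_medications(dispensings, survey_year: int) -> str:
    """Unique ATC level-5 substances dispensed 1 April - 30 September.

    The fixed April-September window of the survey year avoids the
    end-of-year safety-net stockpiling artefact in dispensing data.
    """
    lo = _dt.date(survey_year, 4, 1)
    hi = _dt.date(survey_year, 9, 30)
    seen = set()
    for atc, date in dispensings:
        code = str(atc).strip().upper()
        if not _ATC5_RE.match(code):
            raise RecodeError(f"malformed ATC level-5 code {atc!r} dispensed {date}")
        if lo <= _as_date(date) <= hi:
            seen.add(code)
    return bin_medications(len(seen))


def admission_flags(admissions, survey_return_date) -> tuple[bool, bool, bool]:
    """(any, same-day, overnight) admission flags over the 12-month window.

    Admissions with a pregnancy-related primary diagnosis (ICD-10
    O00-O9A) are excluded before the flags are computed.
    """
    start = _as_date(survey_return_date)
    same_day = overnight = False
    for date, sd_flag, icd10 in admissions:
        if not _in_window(date, start):
            continue
        if is_pregnancy_code(icd10):
            continue
        if sd_flag:
            same_day = True
        else:
            overnight = True
    return same_day or overnight, same_day, overnight


def recode_outcomes(record: ServiceUseRecord) -> OutcomeSet:
    """Full service-use recode for one participant."""
    gp_cat, sp_cat = bin_service_counts(record)
    med_cat = count_unique_medications(record.dispensings, _as_date(record.survey_return_date).year)
    any_adm, sd, on = admission_flags(record.admissions, record.survey_return_date)
    return OutcomeSet(gp_cat, sp_cat, med_cat, any_adm, sd, on)


def recode_outcome_table(
    survey_dates: pd.Series,
    visits: pd.DataFrame,
    dispensings: pd.DataFrame,
    admissions: pd.DataFrame,
) -> pd.DataFrame:
    """Recode long-format service record tables into one outcome row per participant.

    ``survey_dates`` maps participant_id -> survey return date.
    ``visits`` has columns (participant_id, date, provider) with provider
    in {gp, specialist}; ``dispensings`` has (participant_id, atc5, date);
    ``admissions`` has (participant_id, date, same_day, primary_icd10).
    Participants with no rows in a table simply have zero counts.
    """
    by_visit = dict(tuple(visits.groupby("participant_id"))) if len(visits) else {}
    by_disp = dict(tuple(dispensings.groupby("participant_id"))) if len(dispensings) else {}
    by_adm = dict(tuple(admissions.groupby("participant_id"))) if len(admissions) else {}
    rows = []
    for pid, ret in survey_dates.items():
        v = by_visit.get(pid)
        gp_dates, sp_dates = [], []
        if v is not None:
            gp_dates = list(v.loc[v["provider"] == "gp", "date"])
            sp_dates = list(v.loc[v["provider"] == "specialist", "date"])
        d = by_disp.get(pid)
        disp = list(zip(d["atc5"], d["date"])) if d is not None else []
        a = by_adm.get(pid)
        adm = (
            list(zip(a["date"], a["same_day"].astype(bool), a["primary_icd10"]))
            if a is not None
            else []
        )
        rec = ServiceUseRecord(pid, _as_date(ret), gp_dates, sp_dates, disp, adm)
        o = recode_outcomes(rec)
        rows.append(
            {
                "participant_id": pid,
                "gp_category": o.gp_category,
                "specialist_category": o.specialist_category,
                "medication_category": o.medication_category,
                "any_admission": o.any_admission,
                "same_day_admission": o.same_day_admission,
                "overnight_admission": o.overnight_admission,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")
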