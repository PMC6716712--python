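"""Participant records and deterministic covariate-derivation rules.

Implements the epidemiological coding rules of an adult cross-sectional
survey: weekly alcohol grams from standard drinking units, smoking status,
IPAQ short-form physical-activity scoring (MET-min/week and the
low/moderate/high classification), BMI classes, and the ATP-III
metabolic-syndrome criteria count.

All rules are pure functions of the raw questionnaire / laboratory fields,
so the same code derives covariates for real CSV data and for synthetic
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .errors import InvalidInputError, MissingDataError

__all__ = [
    "Sex",
    "AlcoholCategory",
    "SmokingCategory",
    "ActivityCategory",
    "BMIClass",
    "ParticipantRecord",
    "DerivedCovariates",
    "alcohol_grams_per_week",
    "alcohol_category",
    "smoking_category",
    "bmi_and_class",
    "metabolic_syndrome",
    "ipaq_classify",
    "derive_covariates",
    "derive_table",
    "read_cohort_csv",
    "write_derived_csv",
]

# grams of ethanol per standard drinking unit
WINE_GRAMS = 10.0
BEER_GRAMS = 10.0
SPIRIT_GRAMS = 20.0

# IPAQ short-form MET coefficients (official scoring protocol)
MET_WALKING = 3.3
MET_MODERATE = 4.0
MET_VIGOROUS = 8.0


class Sex(str, Enum):
    male = "male"
    female = "female"


class AlcoholCategory(str, Enum):
    abstainer_occasional = "abstainer_occasional"
    light = "light"
    moderate = "moderate"
    heavy = "heavy"


class SmokingCategory(str, Enum):
    never = "never"
    ex_smoker = "ex_smoker"
    smoker = "smoker"


class ActivityCategory(str, Enum):
    low = "low"
    moderate = "moderate"
    high = "high"


class BMIClass(str, Enum):
    normal = "normal"
    overweight = "overweight"
    obese = "obese"


@dataclass
class ParticipantRecord:
    """Raw per-subject measurements and questionnaire answers."""

    id: str
    age: float                      # years, 18-120
    sex: Sex
    wine_glasses_per_week: float
    beers_per_week: float
    spirits_per_week: float
    cigarettes_per_day: float
    years_since_quit: Optional[float]   # None = never quit / never smoked
    ever_smoked: bool
    vigorous_days: int              # 0-7
    moderate_days: int
    walking_days: int
    vigorous_min_per_day: float
    moderate_min_per_day: float
    walking_min_per_day: float
    weight: float                   # kg
    height: float                   # m
    waist: float                    # cm
    triglycerides: float            # mg/dL
    hdl: float                      # mg/dL
    systolic_bp: float              # mm Hg
    diastolic_bp: float             # mm Hg
    on_antihypertensives: bool
    on_antidiabetics: bool
    glucose: float                  # mg/dL
    hemoglobin: float               # g/dL
    mcv: float                      # fL
    esr: float                      # mm/h

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 120):
            raise InvalidInputError(f"age must be in [18, 120], got {self.age}")
        for name in ("vigorous_days", "moderate_days", "walking_days"):
            d = getattr(self, name)
            if not (0 <= d <= 7):
                raise InvalidInputError(f"{name} must be in [0, 7], got {d}")
        for name in (
            "wine_glasses_per_week", "beers_per_week", "spirits_per_week",
            "cigarettes_per_day", "vigorous_min_per_day",
            "moderate_min_per_day", "walking_min_per_day", "esr",
        ):
            v = getattr(self, name)
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v}")
        if isinstance(self.sex, str):
            self.sex = Sex(self.sex)


@dataclass
class DerivedCovariates:
    """Categorical lifestyle/metabolic covariates produced by the coding rules."""

    alcohol_g_per_week: float
    alcohol_category: AlcoholCategory
    smoking_category: SmokingCategory
    met_min_per_week: float
    activity_category: ActivityCategory
    bmi: float
    bmi_class: BMIClass
    metsyn_criteria_count: int
    metabolic_syndrome: bool


def alcohol_grams_per_week(wine_glasses: float, beers: float, spirits: float) -> float:
    """Weekly ethanol grams from standard drinking units.

    A glass of wine and a bottle of beer each carry ~10 g of ethanol, a
    unit of spirits ~20 g.
    """
    if wine_glasses < 0 or beers < 0 or spirits < 0:
        raise InvalidInputError("drink counts must be non-negative")
    return WINE_GRAMS * wine_glasses + BEER_GRAMS * beers + SPIRIT_GRAMS * spirits


def alcohol_category(grams: float) -> AlcoholCategory:
    """Drinking category: 0 / 1-140 / 141-279 / >=280 g per week."""
    if grams < 0:
        raise InvalidInputError(f"grams must be >= 0, got {grams}")
    if grams == 0:
        return AlcoholCategory.abstainer_occasional
    if grams <= 140:
        return AlcoholCategory.light
    if grams <= 279:
        return AlcoholCategory.moderate
    return AlcoholCategory.heavy


def smoking_category(
    cigarettes_per_day: float,
    years_since_quit: Optional[float],
    ever_smoked: bool,
) -> SmokingCategory:
    """Smoker / ex-smoker / never-smoker classification.

    At least one cigarette per day counts as a smoker; so does having quit
    within the preceding year (<= 1 year).  Quitting more than one year
    ago makes an ex-smoker.
    """
    if cigarettes_per_day < 0:
        raise InvalidInputError("cigarettes_per_day must be >= 0")
    if years_since_quit is not None and years_since_quit < 0:
        raise InvalidInputError("years_since_quit must be >= 0")
    if cigarettes_per_day >= 1 and not ever_smoked:
        raise InvalidInputError(
            "contradictory smoking fields: cigarettes_per_day >= 1 but ever_smoked is false"
        )
    if years_since_quit is not None and not ever_smoked:
        raise InvalidInputError(
            "contradictory smoking fields: years_since_quit given but ever_smoked is false"
        )
    if cigarettes_per_day >= 1:
        return SmokingCategory.smoker
    if not ever_smoked:
        return SmokingCategory.never
    if years_since_quit is None:
        # smoked at some point, currently zero per day, no quit date: treat
        # as current non-daily -> ex-smoker is the conservative reading,
        # but the survey records a quit date for every quitter, so this is
        # a contradictory record.
        raise InvalidInputError(
            "contradictory smoking fields: ever_smoked without quit date or current use"
        )
    if years_since_quit <= 1.0:
        return SmokingCategory.smoker
    return SmokingCategory.ex_smoker


def bmi_and_class(weight: float, height: float) -> tuple[float, BMIClass]:
    """BMI (kg/m^2) and its class: normal <25, overweight 25-30, obese >30."""
    if weight <= 0 or height <= 0:
        raise InvalidInputError("weight and height must be positive")
    bmi = weight / height**2
    if bmi < 25.0:
        cls = BMIClass.normal
    elif bmi <= 30.0:
        cls = BMIClass.overweight
    else:
        cls = BMIClass.obese
    return bmi, cls


_METSYN_FIELDS = (
    "waist", "triglycerides", "hdl", "systolic_bp", "diastolic_bp",
    "glucose", "on_antihypertensives", "on_antidiabetics",
)


def metabolic_syndrome(record: ParticipantRecord) -> tuple[int, bool]:
    """ATP-III metabolic-syndrome criteria count and flag (count >= 3).

    The five criteria: abdominal obesity (waist >102 cm male / >88 cm
    female); triglycerides >=150 mg/dL; low HDL (<40 male / <50 female
    mg/dL); blood pressure >=130 systolic or >=85 diastolic or
    antihypertensive use; glucose >=110 mg/dL or antidiabetic therapy.
    """
    for name in _METSYN_FIELDS:
        v = getattr(record, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingDataError(f"metabolic syndrome component missing: {name}")
    male = record.sex == Sex.male
    count = 0
    count += record.waist > (102.0 if male else 88.0)
    count += record.triglycerides >= 150.0
    count += record.hdl < (40.0 if male else 50.0)
    count += (
        record.systolic_bp >= 130.0
        or record.diastolic_bp >= 85.0
        or record.on_antihypertensives
    )
    count += record.glucose >= 110.0 or record.on_antidiabetics
    return count, count >= 3


def ipaq_classify(
    vigorous_days: int, vigorous_min: float,
    moderate_days: int, moderate_min: float,
    walking_days: int, walking_min: float,
) -> tuple[float, ActivityCategory]:
    """IPAQ short-form MET-minutes per week and activity category.

    MET-min/wk sums intensity-weighted activity volume (walking 3.3,
    moderate 4.0, vigorous 8.0 MET).  High: vigorous on >=3 days with
    total >=1500 MET-min/wk, or activity on >=7 days of any combination
    with total >=3000.  Moderate: >=3 days vigorous >=20 min/day, or
    >=5 days moderate-intensity or walking >=30 min/day, or >=5 days of
    any combination with total >=600.  High takes precedence; anything
    else is low.
    """
    for d in (vigorous_days, moderate_days, walking_days):
        if not (0 <= d <= 7):
            raise InvalidInputError(f"activity days must be in [0, 7], got {d}")
    for m in (vigorous_min, moderate_min, walking_min):
        if m < 0:
            raise InvalidInputError("activity minutes must be >= 0")

    met = (
        MET_VIGOROUS * vigorous_days * vigorous_min
        + MET_MODERATE * moderate_days * moderate_min
        + MET_WALKING * walking_days * walking_min
    )
    total_days = vigorous_days + moderate_days + walking_days

    high = (vigorous_days >= 3 and met >= 1500.0) or (total_days >= 7 and met >= 3000.0)
    if high:
        return met, ActivityCategory.high

    # days with >=30 min of moderate-intensity activity and/or walking
    days_30min = (moderate_days if moderate_min >= 30.0 else 0) + (
        walking_days if walking_min >= 30.0 else 0
    )
    moderate = (
        (vigorous_days >= 3 and vigorous_min >= 20.0)
        or days_30min >= 5
        or (total_days >= 5 and met >= 600.0)
    )
    if moderate:
        return met, ActivityCategory.moderate
    return met, ActivityCategory.low


def derive_covariates(record: ParticipantRecord) -> DerivedCovariates:
    """Apply every derivation rule to one participant."""
    grams = alcohol_grams_per_week(
        record.wine_glasses_per_week, record.beers_per_week, record.spirits_per_week
    )
    met, activity = ipaq_classify(
        record.vigorous_days, record.vigorous_min_per_day,
        record.moderate_days, record.moderate_min_per_day,
        record.walking_days, record.walking_min_per_day,
    )
    bmi, bmi_cls = bmi_and_class(record.weight, record.height)
    count, flag = metabolic_syndrome(record)
    return DerivedCovariates(
        alcohol_g_per_week=grams,
        alcohol_category=alcohol_category(grams),
        smoking_category=smoking_category(
            record.cigarettes_per_day, record.years_since_quit, record.ever_smoked
        ),
        met_min_per_week=met,
        activity_category=activity,
        bmi=bmi,
        bmi_class=bmi_cls,
        metsyn_criteria_count=count,
        metabolic_syndrome=flag,
    )


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = ("ever_smoked", "on_antihypertensives", "on_antidiabetics")

_RECORD_COLUMNS = [
    "id", "age", "sex",
    "wine_glasses_per_week", "beers_per_week", "spirits_per_week",
    "cigarettes_per_day", "years_since_quit", "ever_smoked",
    "vigorous_days", "moderate_days", "walking_days",
    "vigorous_min_per_day", "moderate_min_per_day", "walking_min_per_day",
    "weight", "height", "waist", "triglycerides", "hdl",
    "systolic_bp", "diastolic_bp", "on_antihypertensives", "on_antidiabetics",
    "glucose", "hemoglobin", "mcv", "esr",
]


def _row_to_record(row: pd.Series) -> ParticipantRecord:
    ysq = row["years_since_quit"]
    if ysq is None or (isinstance(ysq, float) and math.isnan(ysq)):
        ysq = None
    return ParticipantRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=Sex(row["sex"]),
        wine_glasses_per_week=float(row["wine_glasses_per_week"]),
        beers_per_week=float(row["beers_per_week"]),
        spirits_per_week=float(row["spirits_per_week"]),
        cigarettes_per_day=float(row["cigarettes_per_day"]),
        years_since_quit=None if ysq is None else float(ysq),
        ever_smoked=bool(int(row["ever_smoked"])),
        vigorous_days=int(row["vigorous_days"]),
        moderate_days=int(row["moderate_days"]),
        walking_days=int(row["walking_days"]),
        vigorous_min_per_day=float(row["vigorous_min_per_day"]),
        moderate_min_per_day=float(row["moderate_min_per_day"]),
        walking_min_per_day=float(row["walking_min_per_day"]),
        weight=float(row["weight"]),
        height=float(row["height"]),
        waist=float(row["waist"]),
        triglycerides=float(row["triglycerides"]),
        hdl=float(row["hdl"]),
        systolic_bp=float(row["systolic_bp"]),
        diastolic_bp=float(row["diastolic_bp"]),
        on_antihypertensives=bool(int(row["on_antihypertensives"])),
        on_antidiabetics=bool(int(row["on_antidiabetics"])),
        glucose=float(row["glucose"]),
        hemoglobin=float(row["hemoglobin"]),
        mcv=float(row["mcv"]),
        esr=float(row["esr"]),
    )


def derive_table(cohort: pd.DataFrame, drop_incomplete: bool = True) -> pd.DataFrame:
    """Derive covariates for every row of a cohort table.

    Returns a DataFrame keyed by ``id`` carrying the derived columns plus
    the modelling fields (age, sex, hemoglobin, mcv, esr).  Rows with
    missing required fields are excluded complete-case style when
    ``drop_incomplete`` is true; the number excluded is stored in the
    result's ``attrs["n_excluded"]``.
    """
    missing_cols = [c for c in _RECORD_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise MissingDataError(f"cohort table lacks required columns: {missing_cols}")
    required = [c for c in _RECORD_COLUMNS if c != "years_since_quit"]
    complete = cohort[required].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if not drop_incomplete and n_excluded:
        raise MissingDataError(f"{n_excluded} rows have missing required fields")
    rows = []
    for _, row in cohort.loc[complete].iterrows():
        rec = _row_to_record(row)
        d = derive_covariates(rec)
        rows.append({
            "id": rec.id,
            "age": rec.age,
            "sex": rec.sex.value,
            "alcohol_g_per_week": d.alcohol_g_per_week,
            "alcohol_category": d.alcohol_category.value,
            "smoking_category": d.smoking_category.value,
            "met_min_per_week": d.met_min_per_week,
            "activity_category": d.activity_category.value,
            "bmi": d.bmi,
            "bmi_class": d.bmi_class.value,
            "metsyn_criteria_count": d.metsyn_criteria_count,
            "metabolic_syndrome": d.metabolic_syndrome,
            "hemoglobin": rec.hemoglobin,
            "mcv": rec.mcv,
            "esr": rec.esr,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (sex coded male/female, booleans 0/1)."""
    df = pd.read_csv(path, dtype={"id": str})
    for c in _BOOL_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


def write_derived_csv(derived: pd.DataFrame, path) -> None:
    out = derived.copy()
    if "metabolic_syndrome" in out.columns:
        out["metabolic_syndrome"] = out["metabolic_syndrome"].astype(int)
    out.to_csv(path, index=False)
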