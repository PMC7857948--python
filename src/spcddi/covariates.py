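"""Per-stay covariates for the adjusted odds-ratio models.

Seven covariates enter the multivariable logistic regression besides the
studied drug: age and six laboratory surrogate markers — albumin
(malnutrition), prealbumin (recent malnutrition), creatinine (kidney
failure), ASAT/ALAT (liver failure), TSH (dysthyroidism) and NT-proBNP
(heart failure). Each is categorised against fixed clinical boundaries, and
a missing measurement is imputed with the normal (reference) category: in
routine care an unmeasured parameter is most likely normal, so the data are
treated as not missing at random.

Category boundaries (reference class marked ``ref``):

=============  =======  =============================================
covariate      unit     classes
=============  =======  =============================================
age            years    <70 (ref) / 70-79 / >=80
albumin        g/L      <30 / >=30 (ref)
prealbumin     g/L      <0.07 / 0.07-0.10 / >=0.11 (ref)
creatinine     mg/L     <=15 (ref) / 16-24 / >=25
ASAT or ALAT   IU/L     <250 (ref) / >=250  (max of the two)
TSH            mU/L     0.5-5 (ref) / <0.5 or >5
NT-proBNP      pg/mL    <450 (ref) / >=450
=============  =======  =============================================

The printed integer-style boundaries leave gaps for fractional values
(e.g. creatinine 15.5 mg/L); gaps are assigned to the middle class so that
the labels above stay exact for integer-valued data while the categoriser
remains a total function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

#: covariate -> ordered categories, reference first
CATEGORIES: dict[str, tuple[str, ...]] = {
    "age": ("LT70", "70_79", "GE80"),
    "albumin": ("GE30", "LT30"),
    "prealbumin": ("GE0_11", "0_07_0_10", "LT0_07"),
    "creatinine": ("LE15", "16_24", "GE25"),
    "transaminase": ("LT250", "GE250"),
    "tsh": ("NORMAL_0_5_TO_5", "ABNORMAL"),
    "ntprobnp": ("LT450", "GE450"),
}

REFERENCE = {cov: cats[0] for cov, cats in CATEGORIES.items()}

#: which lab analytes feed each lab-based covariate
COVARIATE_ANALYTES = {
    "albumin": ("ALBUMIN",),
    "prealbumin": ("PREALBUMIN",),
    "creatinine": ("CREATININE",),
    "transaminase": ("ASAT", "ALAT"),
    "tsh": ("TSH",),
    "ntprobnp": ("NTPROBNP",),
}

VALUE_SELECTIONS = ("first", "worst")


def categorize(value: float | None, covariate: str) -> tuple[str, bool]:
    """Category and imputed flag for one covariate value.

    ``None``/NaN maps to the reference category with ``imputed=True``.
    Negative values are invalid.
    """
    if covariate not in CATEGORIES:
        raise KeyError(f"unknown covariate {covariate!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return REFERENCE[covariate], True
    v = float(value)
    if v < 0:
        raise ValueError(f"{covariate} value must be non-negative, got {v}")
    if covariate == "age":
        cat = "LT70" if v < 70 else ("70_79" if v < 80 else "GE80")
    elif covariate == "albumin":
        cat = "LT30" if v < 30 else "GE30"
    elif covariate == "prealbumin":
        cat = "LT0_07" if v < 0.07 else ("0_07_0_10" if v < 0.11 else "GE0_11")
    elif covariate == "creatinine":
        cat = "LE15" if v <= 15 else ("16_24" if v < 25 else "GE25")
    elif covariate == "transaminase":
        cat = "LT250" if v < 250 else "GE250"
    elif covariate == "tsh":
        cat = "NORMAL_0_5_TO_5" if 0.5 <= v <= 5 else "ABNORMAL"
    else:  # ntprobnp
        cat = "LT450" if v < 450 else "GE450"
    return cat, False


@dataclass(frozen=True)
class CovariateProfile:
    """Categorised covariates of one stay (imputed fields are at reference)."""

    stay_id: str
    age_class: str
    albumin_class: str
    prealbumin_class: str
    creatinine_class: str
    transaminase_class: str
    tsh_class: str
    ntprobnp_class: str
    imputed: frozenset[str] = frozenset()


def _select_value(days: np.ndarray, values: np.ndarray, selection: str, covariate: str) -> float:
    if selection == "first":
        return float(values[np.argmin(days)])
    # "worst": the value that lands in the most severe category; ties by first
    order = CATEGORIES[covariate]
    ranks = np.array([order.index(categorize(float(v), covariate)[0]) for v in values])
    worst = np.max(ranks)
    candidates = np.nonzero(ranks == worst)[0]
    return float(values[candidates[np.argmin(days[candidates])]])


def build_profiles(
    subcohort: Cohort, *, value_selection: str = "first"
) -> pd.DataFrame:
    """One covariate profile per stay, as a DataFrame indexed by ``stay_id``.

    For each lab covariate the fed value is, by default, the first
    measurement of the stay (approximating status on admission); ``worst``
    selects the most severe in-stay measurement instead. Transaminase uses
    the maximum of ASAT and ALAT on the selected per-analyte values. Columns
    are ``<covariate>_class`` plus boolean ``<covariate>_imputed`` flags.
    """
    if value_selection not in VALUE_SELECTIONS:
        raise ValueError(f"value_selection must be one of {VALUE_SELECTIONS}")
    labs = subcohort.labs
    analyte_set = {an for ans in COVARIATE_ANALYTES.values() for an in ans}
    relevant = labs[labs.analyte.isin(analyte_set)]
    if (relevant.value < 0).any():
        raise ValueError("covariate lab values must be non-negative")

    # per (stay, analyte) selected value
    if value_selection == "first" and len(relevant):
        first = (
            relevant.sort_values("day", kind="stable")
            .groupby(["stay_id", "analyte"], sort=False)
            .value.first()
        )
        selected = first.to_dict()
    else:
        selected = {}
        for (sid, analyte), g in relevant.groupby(["stay_id", "analyte"]):
            cov = "transaminase" if analyte in ("ASAT", "ALAT") else next(
                c for c, ans in COVARIATE_ANALYTES.items() if analyte in ans
            )
            selected[(sid, analyte)] = _select_value(
                g.day.to_numpy(dtype=int), g.value.to_numpy(dtype=float),
                value_selection, cov,
            )

    stay_ids = subcohort.stays.stay_id.tolist()
    ages = subcohort.stays.age_years.tolist()
    rows = []
    for sid, age in zip(stay_ids, ages):
        row: dict = {"stay_id": sid}
        cat, _ = categorize(float(age), "age")
        row["age_class"] = cat
        row["age_imputed"] = False
        for cov, analytes in COVARIATE_ANALYTES.items():
            values = [selected[(sid, an)] for an in analytes if (sid, an) in selected]
            value = max(values) if values else None  # max only matters for ASAT/ALAT
            cat, imp = categorize(value, cov)
            row[f"{cov}_class"] = cat
            row[f"{cov}_imputed"] = imp
        rows.append(row)
    return pd.DataFrame(rows).set_index("stay_id")


def design_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded covariate design matrix (reference levels omitted).

    Column names are ``<covariate>:<category>``; rows align with the
    profiles' index.
    """
    cols = {}
    for cov, cats in CATEGORIES.items():
        series = profiles[f"{cov}_class"]
        for cat in cats[1:]:
            cols[f"{cov}:{cat}"] = (series == cat).astype(float)
    return pd.DataFrame(cols, index=profiles.index)


def profile_of(profiles: pd.DataFrame, stay_id: str) -> CovariateProfile:
    """Materialise one row of the profiles frame as a :class:`CovariateProfile`."""
    r = profiles.loc[stay_id]
    imputed = frozenset(
        cov for cov in CATEGORIES if r.get(f"{cov}_imputed", False)
    )
    return CovariateProfile(
        stay_id=stay_id,
        age_class=r["age_class"],
        albumin_class=r["albumin_class"],
        prealbumin_class=r["prealbumin_class"],
        creatinine_class=r["creatinine_class"],
        transaminase_class=r["transaminase_class"],
        tsh_class=r["tsh_class"],
        ntprobnp_class=r["ntprobnp_class"],
        imputed=imputed,
    )
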