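"""Longitudinal inpatient EHR tables: reading, validation, inclusion, description.

The analysis consumes three flat tables, one row per record:

``stays``
    one inpatient admission — demographics plus a day-indexed span
    (day 1 = admission day, integer days; daily resolution is all the
    source systems provide for drug administrations);
``administrations``
    one (stay, day, ATC code) daily drug administration;
``labs``
    one (stay, day, analyte, value) laboratory result.

Records are validated against referential and range invariants on read, and
a stay enters the analysis only if it has at least one INR result and at
least one day with a vitamin K antagonist (ATC ``B01AA``) administration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import pct, round_half_up
from .config import DEFAULT_CONFIG, AnalysisConfig

SEXES = ("female", "male")

#: Analytes recognised in the labs table, with their canonical units.
ANALYTES = {
    "INR": "dimensionless",
    "ALBUMIN": "g/L",
    "PREALBUMIN": "g/L",
    "CREATININE": "mg/L",
    "ASAT": "IU/L",
    "ALAT": "IU/L",
    "TSH": "mU/L",
    "NTPROBNP": "pg/mL",
}

STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "hospital_id",
    "admission_day",
    "discharge_day",
    "age_years",
    "sex",
    "died_in_hospital",
]
ADMIN_COLUMNS = ["stay_id", "day", "atc_code"]
LAB_COLUMNS = ["stay_id", "day", "analyte", "value"]

# WHO ATC grammar: letter, 2 digits, 1-2 letters, 2 digits, truncatable at
# each level boundary (e.g. "B01AA", "N05CA", "B01AA03").
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]{1,2}(\d{2})?)?)?$")


def is_valid_atc(code: str) -> bool:
    return bool(_ATC_RE.match(code))


class CohortValidationError(ValueError):
    """Raised when cohort files violate schema or referential invariants.

    ``errors`` holds one human-readable message per offending row, each
    naming the file, the (1-based, header-inclusive) line number and the
    field concerned.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        shown = "\n".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n{shown}{more}")


@dataclass
class Cohort:
    """Validated in-memory cohort: three pandas DataFrames."""

    stays: pd.DataFrame
    administrations: pd.DataFrame
    labs: pd.DataFrame

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    def subset(self, stay_ids: Iterable) -> "Cohort":
        keep = set(stay_ids)
        return Cohort(
            stays=self.stays[self.stays.stay_id.isin(keep)].reset_index(drop=True),
            administrations=self.administrations[
                self.administrations.stay_id.isin(keep)
            ].reset_index(drop=True),
            labs=self.labs[self.labs.stay_id.isin(keep)].reset_index(drop=True),
        )


@dataclass
class InclusionCounts:
    """Bookkeeping of the inclusion filter."""

    total: int
    retained: int
    retained_pct: float  # 100*retained/total, rounded half-up to 2 decimals


def _line(df_index: int) -> int:
    # data row i sits on file line i+2 (header is line 1)
    return int(df_index) + 2


def _coerce_int(df: pd.DataFrame, col: str, fname: str, errors: list[str]) -> None:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() | (coerced != np.floor(coerced.fillna(0)))
    for i in df.index[bad]:
        errors.append(f"{fname} line {_line(i)}: field '{col}' is not an integer: {df.at[i, col]!r}")
    df[col] = coerced.fillna(0).astype(int)


def _validate_stays(stays: pd.DataFrame, errors: list[str]) -> None:
    for col in ("admission_day", "discharge_day", "age_years"):
        _coerce_int(stays, col, "stays", errors)
    dup = stays.stay_id.duplicated(keep=False)
    for i in stays.index[dup]:
        errors.append(f"stays line {_line(i)}: field 'stay_id' duplicated: {stays.at[i, 'stay_id']!r}")
    bad_span = stays.discharge_day < stays.admission_day
    for i in stays.index[bad_span]:
        errors.append(f"stays line {_line(i)}: field 'discharge_day' precedes admission_day")
    bad_age = (stays.age_years < 0) | (stays.age_years > 130)
    for i in stays.index[bad_age]:
        errors.append(f"stays line {_line(i)}: field 'age_years' out of [0, 130]: {stays.at[i, 'age_years']}")
    stays["sex"] = stays.sex.astype(str).str.lower()
    bad_sex = ~stays.sex.isin(SEXES)
    for i in stays.index[bad_sex]:
        errors.append(f"stays line {_line(i)}: field 'sex' not in {SEXES}: {stays.at[i, 'sex']!r}")
    died = stays.died_in_hospital
    if died.dtype != bool:
        mapped = died.astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        for i in stays.index[mapped.isna()]:
            errors.append(f"stays line {_line(i)}: field 'died_in_hospital' not boolean: {died[i]!r}")
        stays["died_in_hospital"] = mapped.fillna(False).astype(bool)


def _validate_refs(
    df: pd.DataFrame, fname: str, spans: pd.DataFrame, errors: list[str]
) -> None:
    """Check stay references and in-span day indices for admins/labs."""
    known = spans.index
    dangling = ~df.stay_id.isin(known)
    for i in df.index[dangling]:
        errors.append(f"{fname} line {_line(i)}: field 'stay_id' references unknown stay {df.at[i, 'stay_id']!r}")
    ok = ~dangling
    if ok.any():
        adm = df.loc[ok, "stay_id"].map(spans.admission_day)
        dis = df.loc[ok, "stay_id"].map(spans.discharge_day)
        out = (df.loc[ok, "day"] < adm) | (df.loc[ok, "day"] > dis)
        for i in out.index[out]:
            errors.append(
                f"{fname} line {_line(i)}: field 'day' ({df.at[i, 'day']}) outside the "
                f"stay span [{adm[i]}, {dis[i]}]"
            )


def validate_cohort(
    stays: pd.DataFrame, administrations: pd.DataFrame, labs: pd.DataFrame
) -> Cohort:
    """Validate the three tables and return a :class:`Cohort`.

    Raises :class:`CohortValidationError` listing every offending row.
    """
    errors: list[str] = []
    stays = stays.copy()
    administrations = administrations.copy()
    labs = labs.copy()

    for df, fname, cols in (
        (stays, "stays", STAY_COLUMNS),
        (administrations, "administrations", ADMIN_COLUMNS),
        (labs, "labs", LAB_COLUMNS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError([f"{fname}: missing column(s) {missing}"])

    _validate_stays(stays, errors)
    # referential checks use the first occurrence of any duplicated stay_id
    spans = (
        stays.drop_duplicates("stay_id").set_index("stay_id")[
            ["admission_day", "discharge_day"]
        ]
    )

    _coerce_int(administrations, "day", "administrations", errors)
    administrations["atc_code"] = administrations.atc_code.astype(str).str.upper()
    bad_atc = ~administrations.atc_code.map(is_valid_atc)
    for i in administrations.index[bad_atc]:
        errors.append(
            f"administrations line {_line(i)}: field 'atc_code' not a valid ATC code: "
            f"{administrations.at[i, 'atc_code']!r}"
        )
    _validate_refs(administrations, "administrations", spans, errors)

    _coerce_int(labs, "day", "labs", errors)
    labs["analyte"] = labs.analyte.astype(str).str.upper()
    bad_an = ~labs.analyte.isin(ANALYTES)
    for i in labs.index[bad_an]:
        errors.append(f"labs line {_line(i)}: field 'analyte' unknown: {labs.at[i, 'analyte']!r}")
    labs["value"] = pd.to_numeric(labs.value, errors="coerce")
    bad_val = labs.value.isna() | (labs.value <= 0)
    for i in labs.index[bad_val]:
        errors.append(f"labs line {_line(i)}: field 'value' must be a positive number: {labs.at[i, 'value']!r}")
    _validate_refs(labs, "labs", spans, errors)

    if errors:
        raise CohortValidationError(errors)
    return Cohort(
        stays.reset_index(drop=True),
        administrations.reset_index(drop=True),
        labs.reset_index(drop=True),
    )


def read_cohort(
    stays_path: str | Path,
    administrations_path: str | Path,
    labs_path: str | Path,
    *,
    delimiter: str = ",",
) -> Cohort:
    """Read and validate the three cohort CSV files."""
    frames = []
    for path in (stays_path, administrations_path, labs_path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"cohort file not found: {path}")
        frames.append(pd.read_csv(path, sep=delimiter, dtype={"stay_id": str}))
    return validate_cohort(*frames)


def write_cohort(
    cohort: Cohort,
    stays_path: str | Path,
    administrations_path: str | Path,
    labs_path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write the cohort back to delimited text (inverse of :func:`read_cohort`)."""
    cohort.stays[STAY_COLUMNS].to_csv(stays_path, sep=delimiter, index=False)
    cohort.administrations[ADMIN_COLUMNS].to_csv(administrations_path, sep=delimiter, index=False)
    cohort.labs[LAB_COLUMNS].to_csv(labs_path, sep=delimiter, index=False)


def apply_inclusion_criteria(
    cohort: Cohort, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[Cohort, InclusionCounts]:
    """Retain stays with >=1 INR result and >=1 VKA administration day.

    Returns the analysed subcohort and an :class:`InclusionCounts` with the
    retained percentage (half-up, 2 decimals).
    """
    has_inr = set(cohort.labs.loc[cohort.labs.analyte == "INR", "stay_id"])
    vka_mask = cohort.administrations.atc_code.str.startswith(config.vka_atc_prefix)
    has_vka = set(cohort.administrations.loc[vka_mask, "stay_id"])
    keep = cohort.stays.stay_id.isin(has_inr & has_vka)
    sub = cohort.subset(cohort.stays.loc[keep, "stay_id"])
    total = cohort.n_stays
    retained = sub.n_stays
    retained_pct = pct(retained, total, 2) if total else 0.0
    return sub, InclusionCounts(total=total, retained=retained, retained_pct=retained_pct)


@dataclass
class CohortSummary:
    """Descriptive summary of an analysed subcohort.

    Percentages are reported both raw and rounded half-up to ``pct_decimals``
    (counts are exact; rounding follows clinical-table convention).
    """

    n_stays: int
    age_mean: float
    age_sd: float
    los_median: float
    los_iqr: tuple[float, float]
    deaths: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)
    vka_molecules: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_stays": self.n_stays,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "los_median": self.los_median,
            "los_iqr": list(self.los_iqr),
            "deaths": self.deaths,
            "sex": self.sex,
            "vka_molecules": self.vka_molecules,
        }


def describe_cohort(
    subcohort: Cohort,
    config: AnalysisConfig = DEFAULT_CONFIG,
    *,
    pct_decimals: int = 2,
) -> CohortSummary:
    """Descriptive statistics of the analysed stays.

    Age is summarised as mean/SD (roughly symmetric in this population),
    length of stay as median/IQR (right-skewed), deaths / sex / VKA molecule
    as counts with percentages. A stay with several distinct VKA codes
    counts once under ``"multiple"`` — the analysis treats VKA as a class.
    """
    if subcohort.n_stays == 0:
        return CohortSummary(
            n_stays=0, age_mean=float("nan"), age_sd=float("nan"),
            los_median=float("nan"), los_iqr=(float("nan"), float("nan")),
            deaths={"count": 0}, sex={}, vka_molecules={},
        )
    stays = subcohort.stays
    n = len(stays)
    los = stays.discharge_day - stays.admission_day + 1
    q1, q3 = np.percentile(los, [25, 75])

    def cat(count: int) -> dict:
        return {
            "count": int(count),
            "pct_raw": 100.0 * count / n,
            "pct": pct(int(count), n, pct_decimals),
        }

    deaths = cat(int(stays.died_in_hospital.sum()))
    sex = {s: cat(int((stays.sex == s).sum())) for s in SEXES}

    admins = subcohort.administrations
    vka = admins[admins.atc_code.str.startswith(config.vka_atc_prefix)]
    per_stay = vka.groupby("stay_id").atc_code.agg(lambda s: tuple(sorted(set(s))))
    molecule = per_stay.map(lambda codes: codes[0] if len(codes) == 1 else "multiple")
    vka_molecules = {code: cat(int(cnt)) for code, cnt in molecule.value_counts().items()}

    return CohortSummary(
        n_stays=n,
        age_mean=round_half_up(float(stays.age_years.mean()), 1),
        age_sd=round_half_up(float(stays.age_years.std(ddof=1)) if n > 1 else 0.0, 1),
        los_median=float(np.median(los)),
        los_iqr=(float(q1), float(q3)),
        deaths=deaths,
        sex=sex,
        vka_molecules=vka_molecules,
    )
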