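"""Seeded synthetic-EHR cohort generator with serialized ground truth.

The generator emulates the statistical structure the alert-filtering
analysis assumes: inpatient stays with demographics calibrated to the study
population (mean age 75.9 y, SD 12.0; 58.2 % women; median length of stay
9 days, IQR 6-15; a fluindione-dominant VKA mix), one VKA episode per stay,
optional companion-drug episodes, covariate labs with missingness, and INR
trajectories whose excursion odds follow a configurable logistic model.

Outcome mechanism
-----------------
Outcomes are generated *at the analysis-window level on the logistic
scale*, not from a pharmacokinetic INR model: for each stay, latent
indicators for the high excursion (INR at or above the potentiation
threshold) and the low excursion are drawn from

    logit P(outcome) = beta_0 + beta_drug * exposed + sum(covariate effects)

and, when an outcome fires, an INR value beyond the relevant threshold is
placed uniformly at random on a day inside the stay's analytic window
(computed with the same window rules as the exposure engine); otherwise all
in-window INR values lie strictly between the two thresholds. Injected
log-ORs are therefore exact on the scale the estimators work on, which
makes parameter-recovery tests well-posed.

Each stay carries *at most one* companion (rulebook) drug episode. With a
single latent outcome per excursion type, per-rule windows can only agree
with the latent model if a stay's outcome day lies inside every relevant
window; restricting to one companion drug (whose exposed window is nested
in the VKA window every nonexposed rule uses) guarantees that consistency
while keeping the windows realistic. Simulated cohorts consequently contain
no cross-rule contamination from concomitant interacting drugs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .cohort import Cohort, validate_cohort, write_cohort
from .config import DEFAULT_CONFIG, AnalysisConfig
from .covariates import categorize

_POT = "potentiates_vka"
_INH = "inhibits_vka"


@dataclass(frozen=True)
class DrugSpec:
    """Ground-truth behaviour of one companion drug."""

    label: str
    atc_code: str
    direction: str  # potentiates_vka | inhibits_vka
    exposure_prevalence: float = 0.2
    co_administration_probability: float = 0.8
    true_log_or_initiation: float = 0.0
    true_log_or_discontinuation: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (_POT, _INH):
            raise ValueError("drug direction must be potentiates_vka or inhibits_vka")
        for p in (self.exposure_prevalence, self.co_administration_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


#: lab value ranges: (reference range, abnormal ranges) per analyte
_LAB_RANGES = {
    "ALBUMIN": ((30.0, 45.0), [(18.0, 29.9)]),
    "PREALBUMIN": ((0.11, 0.35), [(0.02, 0.069), (0.071, 0.105)]),
    "CREATININE": ((5.0, 15.0), [(15.6, 24.4), (25.0, 60.0)]),
    "ASAT": ((10.0, 100.0), [(250.0, 900.0)]),
    "ALAT": ((10.0, 100.0), [(250.0, 900.0)]),
    "TSH": ((0.5, 5.0), [(0.05, 0.45), (5.5, 30.0)]),
    "NTPROBNP": ((50.0, 440.0), [(450.0, 8000.0)]),
}

_DEFAULT_MISSINGNESS = {
    "ALBUMIN": 0.3,
    "PREALBUMIN": 0.7,
    "CREATININE": 0.1,
    "ASAT": 0.2,
    "ALAT": 0.2,
    "TSH": 0.6,
    "NTPROBNP": 0.7,
}

#: which covariate each analyte feeds (ASAT/ALAT jointly feed transaminase)
_ANALYTE_COVARIATE = {
    "ALBUMIN": "albumin",
    "PREALBUMIN": "prealbumin",
    "CREATININE": "creatinine",
    "TSH": "tsh",
    "NTPROBNP": "ntprobnp",
}


@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Demographic defaults reproduce the source population's descriptive
    statistics; everything else is configurable ground truth.
    ``covariate_effects`` maps ``"covariate:CATEGORY"`` to a log-OR applied
    to both excursion types (default: no covariate effects, so that the
    injected drug log-ORs are identical on the marginal and
    covariate-conditional scales — logistic ORs are non-collapsible
    otherwise).
    """

    n_stays: int = 1000
    seed: int = 0
    age_mean: float = 75.9
    age_sd: float = 12.0
    female_fraction: float = 0.582
    los_median: float = 9.0
    los_iqr: tuple[float, float] = (6.0, 15.0)
    death_rate: float = 0.04
    vka_mix: dict = field(
        default_factory=lambda: {
            "B01AA12": 0.805,  # fluindione
            "B01AA03": 0.137,  # warfarin
            "B01AA07": 0.056,  # acenocoumarol
            "B01AA02": 0.002,  # other VKA
        }
    )
    drug_specs: list = field(default_factory=list)
    baseline_outcome_rate_high: float = 0.10
    baseline_outcome_rate_low: float = 0.10
    covariate_effects: dict = field(default_factory=dict)
    lab_abnormal_rate: float = 0.2
    lab_missingness: dict = field(default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    inr_measurement_rate: float = 0.4
    noise_drug_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        total_prev = sum(d.exposure_prevalence for d in self.drug_specs)
        if total_prev > 1.0 + 1e-9:
            raise ValueError("drug exposure prevalences must sum to <= 1 "
                             "(at most one companion drug per stay)")
        for p in (
            self.female_fraction, self.death_rate, self.baseline_outcome_rate_high,
            self.baseline_outcome_rate_low, self.inr_measurement_rate,
            self.lab_abnormal_rate, self.noise_drug_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.vka_mix.values()) - 1.0) > 1e-6:
            raise ValueError("vka_mix must sum to 1")


@dataclass
class SimulationTruth:
    """Serializable ground truth sufficient to score any estimator."""

    drugs: list[dict]
    stays: list[dict]
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1), encoding="utf-8")


def _los_sigma(median: float, iqr: tuple[float, float]) -> float:
    """Lognormal sigma matching the printed LOS quartiles (mu = ln median)."""
    z = norm.ppf(0.75)
    q1, q3 = iqr

    def loss(sigma: float) -> float:
        lo = median * math.exp(-z * sigma)
        hi = median * math.exp(z * sigma)
        return (lo - q1) ** 2 + (hi - q3) ** 2

    res = minimize_scalar(loss, bounds=(0.05, 3.0), method="bounded")
    return float(res.x)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_cohort(
    config: SimulationConfig,
    analysis: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[Cohort, SimulationTruth]:
    """Generate a validated cohort plus its ground truth.

    Deterministic given ``config.seed``. Every stay receives a VKA episode
    and at least one INR measurement, so the whole cohort passes the
    inclusion criteria by construction.
    """
    onset, offset = analysis.onset_lag_days, analysis.offset_lag_days
    min_los = 3
    if onset + 1 >= min_los + offset:
        raise ValueError(
            f"onset lag {onset} leaves no observable window for the shortest "
            f"stays (LOS {min_los}); incompatible configuration"
        )
    rng = np.random.default_rng(config.seed)
    sigma = _los_sigma(config.los_median, config.los_iqr)

    vka_codes = list(config.vka_mix)
    vka_probs = np.array([config.vka_mix[c] for c in vka_codes], dtype=float)
    vka_probs = vka_probs / vka_probs.sum()

    prev = np.array([d.exposure_prevalence for d in config.drug_specs], dtype=float)
    prev_cum = np.cumsum(prev)

    b0_high = _logit(config.baseline_outcome_rate_high)
    b0_low = _logit(config.baseline_outcome_rate_low)

    stays_rows, admin_rows, lab_rows, truth_stays = [], [], [], []
    n_exp_init = np.zeros(len(config.drug_specs), dtype=int)
    n_exp_disc = np.zeros(len(config.drug_specs), dtype=int)

    for i in range(config.n_stays):
        sid = f"S{i + 1:06d}"
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 105))
        sex = "female" if rng.random() < config.female_fraction else "male"
        los = int(np.clip(round(rng.lognormal(math.log(config.los_median), sigma)), min_los, 90))
        died = bool(rng.random() < config.death_rate)
        stays_rows.append((sid, f"P{i + 1:06d}", "H1", 1, los, age, sex, died))

        # single VKA episode spanning most of the stay
        v1 = 1 + int(rng.integers(0, min(2, los - min_los) + 1))
        v2 = los - int(rng.integers(0, max(0, min(2, los - v1 - 2)) + 1))
        vka_code = vka_codes[int(rng.choice(len(vka_codes), p=vka_probs))]
        for day in range(v1, v2 + 1):
            admin_rows.append((sid, day, vka_code))

        # at most one companion drug episode
        u = rng.random()
        drug_idx = int(np.searchsorted(prev_cum, u)) if len(prev_cum) else len(prev_cum)
        drug = config.drug_specs[drug_idx] if drug_idx < len(config.drug_specs) else None
        init_exposed = disc_exposed = False
        d_start = d_end = None
        if drug is not None:
            if rng.random() < drug.co_administration_probability:
                d_start = int(rng.integers(v1, v2))  # leaves room for an end day
                d_end = int(rng.integers(d_start, v2 + 1))
                init_exposed = True
                disc_exposed = d_end < v2
            elif v2 < los:  # drug present but never on a VKA day
                d_start = v2 + 1
                d_end = min(v2 + 2, los)
            if d_start is not None:
                for day in range(d_start, d_end + 1):
                    admin_rows.append((sid, day, drug.atc_code))
        if init_exposed:
            n_exp_init[drug_idx] += 1
        if disc_exposed:
            n_exp_disc[drug_idx] += 1

        # covariate labs with missingness; effects accumulate on both logits
        cov_lp = 0.0
        age_cat, _ = categorize(float(age), "age")
        cov_lp += config.covariate_effects.get(f"age:{age_cat}", 0.0)
        transaminase_vals = []
        for analyte, (ref_rng, abn_rngs) in _LAB_RANGES.items():
            if rng.random() < config.lab_missingness.get(analyte, 0.0):
                continue
            day = int(rng.integers(1, los + 1))
            if rng.random() < config.lab_abnormal_rate:
                lo, hi = abn_rngs[int(rng.integers(0, len(abn_rngs)))]
            else:
                lo, hi = ref_rng
            value = float(round(rng.uniform(lo, hi), 3))
            lab_rows.append((sid, day, analyte, value))
            if analyte in ("ASAT", "ALAT"):
                transaminase_vals.append(value)
            else:
                cov = _ANALYTE_COVARIATE[analyte]
                cat, _ = categorize(value, cov)
                cov_lp += config.covariate_effects.get(f"{cov}:{cat}", 0.0)
        if transaminase_vals:
            cat, _ = categorize(max(transaminase_vals), "transaminase")
            cov_lp += config.covariate_effects.get(f"transaminase:{cat}", 0.0)

        # latent excursion indicators on the logistic scale
        lp_high, lp_low = b0_high + cov_lp, b0_low + cov_lp
        if drug is not None and init_exposed:
            if drug.direction == _POT:
                lp_high += drug.true_log_or_initiation
            else:
                lp_low += drug.true_log_or_initiation
        if drug is not None and disc_exposed:
            if drug.direction == _POT:
                lp_low += drug.true_log_or_discontinuation
            else:
                lp_high += drug.true_log_or_discontinuation
        out_high = bool(rng.random() < _sigmoid(lp_high))
        out_low = bool(rng.random() < _sigmoid(lp_low))

        # analytic windows, mirroring the exposure engine
        vka_win = (v1 + onset, min(v2 + offset, los))
        init_win = (d_start + onset, min(d_end + offset, los)) if init_exposed else None
        disc_win = (
            (d_end + onset, min(d_end + offset, v2 + offset, los)) if disc_exposed else None
        )

        def _target(primary):
            if primary is not None and primary[0] <= primary[1]:
                return primary
            return vka_win if vka_win[0] <= vka_win[1] else None

        # the window in which each latent excursion must be observable
        if drug is not None and init_exposed and drug.direction == _POT:
            tgt_high = _target(init_win)
        elif drug is not None and disc_exposed and drug.direction == _INH:
            tgt_high = _target(disc_win)
        else:
            tgt_high = _target(None)
        if drug is not None and init_exposed and drug.direction == _INH:
            tgt_low = _target(init_win)
        elif drug is not None and disc_exposed and drug.direction == _POT:
            tgt_low = _target(disc_win)
        else:
            tgt_low = _target(None)

        if out_high and tgt_high is not None:
            day = int(rng.integers(tgt_high[0], tgt_high[1] + 1))
            lab_rows.append((sid, day, "INR", float(round(rng.uniform(5.0, 8.0), 2))))
        elif tgt_high is None:
            out_high = False
        if out_low and tgt_low is not None:
            day = int(rng.integers(tgt_low[0], tgt_low[1] + 1))
            lab_rows.append((sid, day, "INR", float(round(rng.uniform(0.8, 1.5), 2))))
        elif tgt_low is None:
            out_low = False

        # background INR strictly inside the two thresholds
        lab_rows.append((sid, v1, "INR", float(round(rng.uniform(1.8, 4.5), 2))))
        for day in range(1, los + 1):
            if rng.random() < config.inr_measurement_rate:
                lab_rows.append((sid, day, "INR", float(round(rng.uniform(1.8, 4.5), 2))))

        if rng.random() < config.noise_drug_rate:
            admin_rows.append((sid, int(rng.integers(1, los + 1)), "V06DX01"))

        truth_stays.append(
            {
                "stay_id": sid,
                "drug": drug.label if drug is not None else None,
                "init_exposed": init_exposed,
                "disc_exposed": disc_exposed,
                "outcome_high": out_high,
                "outcome_low": out_low,
            }
        )

    stays = pd.DataFrame(
        stays_rows,
        columns=[
            "stay_id", "patient_id", "hospital_id", "admission_day",
            "discharge_day", "age_years", "sex", "died_in_hospital",
        ],
    )
    admins = pd.DataFrame(admin_rows, columns=["stay_id", "day", "atc_code"])
    labs = pd.DataFrame(lab_rows, columns=["stay_id", "day", "analyte", "value"])
    cohort = validate_cohort(stays, admins, labs)

    truth = SimulationTruth(
        drugs=[
            {
                **dataclasses.asdict(d),
                "n_exposed_initiation": int(n_exp_init[k]),
                "n_exposed_discontinuation": int(n_exp_disc[k]),
            }
            for k, d in enumerate(config.drug_specs)
        ],
        stays=truth_stays,
        config={
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("drug_specs",)
            },
            "los_iqr": list(config.los_iqr),
        },
    )
    return cohort, truth


@dataclass
class FixtureCohort:
    """Tiny hand-checkable cohort with every window edge case.

    ``expected_windows`` maps (stay_id, phase) to the hand-traced
    (status, start_day, end_day, outcome) tuple for the tramadol rules;
    ``expected_tables`` maps phase to the hand-counted (a, b, c, d).
    """

    cohort: Cohort
    rulebook: list
    rules: list
    included_stay_ids: list[str]
    excluded_stay_ids: list[str]
    expected_windows: dict
    expected_tables: dict


def make_fixture_cohort() -> FixtureCohort:
    """Deterministic 8-stay cohort exercising the window edge cases.

    One potentiating companion drug (tramadol, N02AX02) against a fluindione
    VKA episode. Covered edge cases: co-administration, drug stopped on the
    VKA's last day (not exposed for discontinuation), no overlap, window
    truncation at discharge, a VKA given on the discharge day only
    (degenerate window, dropped), interrupted co-administration (only the
    first run counts), boundary INR values exactly 5.0 and 1.5 (inclusive
    thresholds), an INR excursion before the window start (ignored), and
    two stays failing the inclusion criteria.
    """
    from .rulebook import DrugEntry, expand_rules

    VKA = "B01AA12"
    TRAM = "N02AX02"

    def stay(sid, discharge, age, sex="female", died=False):
        return (sid, f"P_{sid}", "H1", 1, discharge, age, sex, died)

    stays = pd.DataFrame(
        [
            stay("S1", 12, 65),
            stay("S2", 12, 72, "male"),
            stay("S3", 10, 81),
            stay("S4", 10, 70, "male"),
            stay("S5", 12, 88, "female", died=True),
            stay("S6", 9, 59, "male"),
            stay("S7", 6, 77),   # no VKA -> excluded
            stay("S8", 6, 69),   # no INR -> excluded
        ],
        columns=[
            "stay_id", "patient_id", "hospital_id", "admission_day",
            "discharge_day", "age_years", "sex", "died_in_hospital",
        ],
    )

    admin_rows = []
    for day in range(1, 11):
        admin_rows.append(("S1", day, VKA))
        admin_rows.append(("S2", day, VKA))
    admin_rows += [("S1", d, TRAM) for d in range(3, 7)]
    admin_rows += [("S2", d, TRAM) for d in range(3, 11)]  # stops on VKA's last day
    admin_rows += [("S3", d, VKA) for d in range(1, 6)]
    admin_rows += [("S3", d, TRAM) for d in range(6, 10)]  # no overlap
    admin_rows += [("S4", 10, VKA)]  # VKA on discharge day only
    admin_rows += [("S5", d, VKA) for d in range(2, 6)]
    admin_rows += [("S6", d, VKA) for d in range(1, 9)]
    admin_rows += [("S6", d, TRAM) for d in (2, 3, 4, 6, 7)]  # interrupted run
    admin_rows += [("S7", 2, TRAM), ("S7", 3, TRAM)]
    admin_rows += [("S8", d, VKA) for d in (2, 3, 4)]
    admins = pd.DataFrame(admin_rows, columns=["stay_id", "day", "atc_code"])

    labs = pd.DataFrame(
        [
            ("S1", 2, "INR", 2.5),
            ("S1", 3, "INR", 6.2),   # before the exposed window [4, 10]
            ("S1", 7, "INR", 5.0),   # boundary: counts as potentiation
            ("S1", 2, "ALBUMIN", 28.0),
            ("S1", 8, "ALBUMIN", 33.0),  # first-value selection -> LT30
            ("S2", 5, "INR", 2.0),
            ("S2", 11, "INR", 1.5),  # boundary: counts as inhibition
            ("S2", 3, "CREATININE", 15.0),
            ("S3", 4, "INR", 2.2),
            ("S4", 5, "INR", 2.0),
            ("S5", 5, "INR", 4.9),
            ("S6", 8, "INR", 5.5),
            ("S7", 2, "INR", 2.5),
        ],
        columns=["stay_id", "day", "analyte", "value"],
    )

    cohort = validate_cohort(stays, admins, labs)
    rulebook = [
        DrugEntry(
            label="tramadol",
            direction=_POT,
            atc_codes=frozenset({TRAM}),
            group="analgesic_immunologic",
        )
    ]
    rules = expand_rules(rulebook)

    expected_windows = {
        # (stay_id, phase): (status, start, end, outcome)
        ("S1", "initiation"): ("exposed", 4, 10, True),
        ("S2", "initiation"): ("exposed", 4, 12, False),
        ("S3", "initiation"): ("nonexposed", 2, 9, False),
        ("S4", "initiation"): ("not_applicable", None, None, None),
        ("S5", "initiation"): ("nonexposed", 3, 9, False),
        ("S6", "initiation"): ("exposed", 3, 8, True),
        ("S1", "discontinuation"): ("exposed", 7, 10, False),
        ("S2", "discontinuation"): ("nonexposed", 2, 12, True),
        ("S3", "discontinuation"): ("nonexposed", 2, 9, False),
        ("S4", "discontinuation"): ("not_applicable", None, None, None),
        ("S5", "discontinuation"): ("nonexposed", 3, 9, False),
        ("S6", "discontinuation"): ("exposed", 8, 9, False),
    }
    expected_tables = {
        "initiation": (2, 1, 0, 2),       # n_exposed = 3: estimable boundary
        "discontinuation": (0, 2, 1, 2),  # n_exposed = 2: insufficient data
    }
    return FixtureCohort(
        cohort=cohort,
        rulebook=rulebook,
        rules=rules,
        included_stay_ids=["S1", "S2", "S3", "S4", "S5", "S6"],
        excluded_stay_ids=["S7", "S8"],
        expected_windows=expected_windows,
        expected_tables=expected_tables,
    )


def write_simulation(
    cohort: Cohort, truth: SimulationTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write stays/administrations/labs CSVs plus truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stays": out / "stays.csv",
        "administrations": out / "administrations.csv",
        "labs": out / "labs.csv",
        "truth": out / "truth.json",
    }
    write_cohort(cohort, paths["stays"], paths["administrations"], paths["labs"])
    truth.to_json(paths["truth"])
    return paths
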