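"""Per-rule exposure classification, observation windows and outcome detection.

For every (stay, rule) pair the engine decides whether the stay is exposed,
builds the day interval in which the INR excursion is sought, and detects
the outcome. All intervals are inclusive integer day ranges; day 1 is the
admission day.

Window semantics (onset lag 1 day, residual-action lag 4 days by default):

* exposed, initiation rule — the window opens the day after the first
  co-administration day of the VKA and the interacting drug, and closes
  ``offset_lag_days`` after the last day of the first uninterrupted
  co-administration run (later re-initiations are ignored), truncated at
  discharge;
* exposed, discontinuation rule — a stay is exposed when the interacting
  drug's last administration precedes the VKA's last administration (the
  drug stopped while the VKA continued); the window opens the day after the
  drug's last administration and closes ``offset_lag_days`` later, capped by
  the VKA's own residual window and by discharge;
* nonexposed (either phase) — the window opens the day after the first VKA
  administration and closes ``offset_lag_days`` after the last one,
  truncated at discharge.

A window whose start exceeds its end carries no observable days; the stay
is then dropped from that rule's contingency table (``not_applicable``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import DEFAULT_CONFIG, AnalysisConfig
from .rulebook import DDIRule, DrugEntry

EXPOSED = "exposed"
NONEXPOSED = "nonexposed"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ObservationWindow:
    stay_id: str
    rule_id: str
    exposure_status: str
    start_day: int | None = None
    end_day: int | None = None

    def __post_init__(self) -> None:
        if self.exposure_status == NOT_APPLICABLE:
            if self.start_day is not None or self.end_day is not None:
                raise ValueError("not_applicable windows carry no day interval")
        else:
            if self.start_day is None or self.end_day is None or self.start_day > self.end_day:
                raise ValueError("applicable windows need start_day <= end_day")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome table.

    ``a`` exposed with outcome, ``b`` exposed without, ``c`` nonexposed with
    outcome, ``d`` nonexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def match_drug_days(administrations: pd.DataFrame, drug: DrugEntry) -> pd.DataFrame:
    """Rows of ``administrations`` matching the entry's ATC codes.

    ``exact`` entries match codes verbatim; ``prefix`` entries (class-level,
    e.g. barbiturates ``N05CA``) match any code starting with one of them.
    """
    atc = administrations.atc_code
    if drug.match_mode == "prefix":
        mask = np.zeros(len(administrations), dtype=bool)
        for code in drug.atc_codes:
            mask |= atc.str.startswith(code).to_numpy()
    else:
        mask = atc.isin(drug.atc_codes).to_numpy()
    return administrations[mask]


def _first_run_end(days: np.ndarray) -> int:
    """Last day of the first run of consecutive days in a sorted unique array."""
    breaks = np.nonzero(np.diff(days) > 1)[0]
    return int(days[breaks[0]] if len(breaks) else days[-1])


def classify_exposure(
    vka_days: np.ndarray,
    drug_days: np.ndarray,
    phase: str,
) -> str:
    """Exposure status of one stay for one rule.

    ``vka_days`` / ``drug_days`` are the (sorted, unique) administration day
    indices of the VKA class and of the rule's drug during the stay.
    Initiation: exposed iff at least one day carries both. Discontinuation:
    additionally, the drug's last administration must precede the VKA's last
    (the drug stopped under continuing VKA).
    """
    if len(vka_days) == 0 or len(drug_days) == 0:
        return NONEXPOSED
    co_days = np.intersect1d(vka_days, drug_days, assume_unique=True)
    if len(co_days) == 0:
        return NONEXPOSED
    if phase == "discontinuation" and not drug_days[-1] < vka_days[-1]:
        return NONEXPOSED
    return EXPOSED


def build_window(
    stay_id: str,
    rule: DDIRule,
    exposure_status: str,
    vka_days: np.ndarray,
    drug_days: np.ndarray,
    discharge_day: int,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ObservationWindow:
    """Observation window for one (stay, rule) given its exposure status."""
    onset, offset = config.onset_lag_days, config.offset_lag_days
    if exposure_status == EXPOSED:
        if rule.phase == "initiation":
            co_days = np.intersect1d(vka_days, drug_days, assume_unique=True)
            start = int(co_days[0]) + onset
            end = min(_first_run_end(co_days) + offset, discharge_day)
        else:
            drug_last = int(drug_days[-1])
            start = drug_last + onset
            end = min(drug_last + offset, int(vka_days[-1]) + offset, discharge_day)
    else:
        start = int(vka_days[0]) + onset
        end = min(int(vka_days[-1]) + offset, discharge_day)
    if start > end:
        return ObservationWindow(stay_id, rule.rule_id, NOT_APPLICABLE)
    return ObservationWindow(stay_id, rule.rule_id, exposure_status, start, end)


def detect_outcome(
    window: ObservationWindow,
    inr_days: np.ndarray,
    inr_values: np.ndarray,
    expected_outcome: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> bool:
    """True iff an in-window INR crosses the rule's threshold (inclusive)."""
    if window.exposure_status == NOT_APPLICABLE:
        raise ValueError("cannot search a window with no day interval")
    in_win = (inr_days >= window.start_day) & (inr_days <= window.end_day)
    if not in_win.any():
        return False
    values = inr_values[in_win]
    if expected_outcome == "INR_GE_HIGH":
        return bool((values >= config.inr_high_threshold).any())
    return bool((values <= config.inr_low_threshold).any())


def _split_by_stay(stay_ids: np.ndarray, *arrays: np.ndarray) -> dict:
    """Group parallel arrays by stay id (single stable sort, no pandas groupby)."""
    if len(stay_ids) == 0:
        return {}
    order = np.argsort(stay_ids, kind="stable")
    sids = stay_ids[order]
    bounds = np.nonzero(sids[1:] != sids[:-1])[0] + 1
    keys = sids[np.r_[0, bounds]] if len(bounds) else sids[:1]
    parts = [np.split(arr[order], bounds) for arr in arrays]
    if len(arrays) == 1:
        return dict(zip(keys, parts[0]))
    return {k: tuple(p[i] for p in parts) for i, k in enumerate(keys)}


def _day_sets(frame: pd.DataFrame) -> dict:
    grouped = _split_by_stay(frame.stay_id.to_numpy(), frame.day.to_numpy(dtype=int))
    return {sid: np.unique(days) for sid, days in grouped.items()}


class _CohortIndex:
    """Per-stay day/value arrays, built once per cohort and reused across rules."""

    def __init__(self, subcohort: Cohort, config: AnalysisConfig):
        self.config = config
        stays = subcohort.stays
        self.stay_ids = stays.stay_id.tolist()
        self.discharge = dict(zip(stays.stay_id, stays.discharge_day.astype(int)))
        admins = subcohort.administrations
        vka = admins[admins.atc_code.str.startswith(config.vka_atc_prefix)]
        self.vka_days = _day_sets(vka)
        self._admins = admins
        inr = subcohort.labs[subcohort.labs.analyte == "INR"]
        self.inr = _split_by_stay(
            inr.stay_id.to_numpy(),
            inr.day.to_numpy(dtype=int),
            inr.value.to_numpy(dtype=float),
        )
        self._empty = np.empty(0, dtype=int)
        self._drug_cache: dict = {}

    def drug_days(self, drug: DrugEntry) -> dict:
        key = (drug.atc_codes, drug.match_mode)
        if key not in self._drug_cache:
            self._drug_cache[key] = _day_sets(match_drug_days(self._admins, drug))
        return self._drug_cache[key]


def assemble_table(
    subcohort: Cohort,
    rule: DDIRule,
    config: AnalysisConfig = DEFAULT_CONFIG,
    *,
    index: _CohortIndex | None = None,
    return_windows: bool = False,
):
    """Per-rule 2x2 table over all included stays.

    Each stay with an applicable window contributes to exactly one cell;
    ``not_applicable`` stays are dropped. Returns ``(table, n_exposed)``, or
    ``(table, n_exposed, windows)`` with per-stay audit records when
    ``return_windows`` is set.
    """
    idx = index if index is not None else _CohortIndex(subcohort, config)
    drug_days_by_stay = idx.drug_days(rule.drug)
    empty = idx._empty
    a = b = c = d = 0
    windows: list[tuple] = []
    for sid in idx.stay_ids:
        vka_days = idx.vka_days.get(sid, empty)
        if len(vka_days) == 0:
            continue  # cannot happen after inclusion filtering
        drug_days = drug_days_by_stay.get(sid, empty)
        status = classify_exposure(vka_days, drug_days, rule.phase)
        window = build_window(
            sid, rule, status, vka_days, drug_days, idx.discharge[sid], config
        )
        if window.exposure_status == NOT_APPLICABLE:
            if return_windows:
                windows.append((sid, rule.rule_id, NOT_APPLICABLE, None, None, None))
            continue
        inr_days, inr_values = idx.inr.get(sid, (empty, empty))
        outcome = detect_outcome(window, inr_days, inr_values, rule.expected_outcome, config)
        if status == EXPOSED:
            a += outcome
            b += not outcome
        else:
            c += outcome
            d += not outcome
        if return_windows:
            windows.append(
                (sid, rule.rule_id, status, window.start_day, window.end_day, bool(outcome))
            )
    table = ContingencyTable(a, b, c, d)
    if return_windows:
        return table, table.n_exposed, windows
    return table, table.n_exposed


def windows_to_frame(windows: list[tuple]) -> pd.DataFrame:
    """Audit dump of per-(stay, rule) windows as a DataFrame."""
    return pd.DataFrame(
        windows,
        columns=["stay_id", "rule_id", "status", "start_day", "end_day", "outcome"],
    )
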