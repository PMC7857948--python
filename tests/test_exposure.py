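"""Exposure classification, window construction, outcome detection, tables.

Includes an independent brute-force oracle that re-derives each rule's
contingency table by enumerating (stay, day, lab) triples with plain Python
sets and loops, with no shared code with the engine under test.
"""

import numpy as np
import pandas as pd
import pytest

import spcddi as sp
from spcddi.config import AnalysisConfig
from spcddi.exposure import EXPOSED, NONEXPOSED, NOT_APPLICABLE, _first_run_end
from spcddi.rulebook import DrugEntry


def days(*d):
    return np.array(d, dtype=int)


def make_rule(phase, outcome="INR_GE_HIGH", codes=("N02AX02",), match_mode="exact"):
    drug = DrugEntry(
        label="probe", direction="potentiates_vka",
        atc_codes=frozenset(codes), match_mode=match_mode,
    )
    return sp.DDIRule(rule_id=f"probe::{phase}", drug=drug, phase=phase,
                      expected_outcome=outcome)


class TestClassify:
    def test_co_administration_day_means_exposed(self):
        assert sp.classify_exposure(days(*range(1, 11)), days(3, 4, 5, 6), "initiation") == EXPOSED

    def test_drug_stopping_before_vka_is_discontinuation_exposed(self):
        assert sp.classify_exposure(days(*range(1, 11)), days(3, 4, 5, 6), "discontinuation") == EXPOSED

    def test_drug_stopping_with_vka_not_discontinuation_exposed(self):
        assert sp.classify_exposure(days(*range(1, 11)), days(3, 10), "discontinuation") == NONEXPOSED

    def test_no_overlap_is_nonexposed_in_both_phases(self):
        for phase in ("initiation", "discontinuation"):
            assert sp.classify_exposure(days(1, 2, 3, 4, 5), days(6, 7, 8, 9), phase) == NONEXPOSED

    def test_no_drug_at_all(self):
        assert sp.classify_exposure(days(1, 2, 3), days(), "initiation") == NONEXPOSED


class TestBuildWindow:
    def test_exposed_initiation_window(self):
        w = sp.build_window("S", make_rule("initiation"), EXPOSED,
                            days(*range(1, 11)), days(3, 4, 5, 6), discharge_day=12)
        assert (w.start_day, w.end_day) == (4, 10)

    def test_nonexposed_window(self):
        w = sp.build_window("S", make_rule("initiation"), NONEXPOSED,
                            days(2, 3, 4, 5), days(), discharge_day=12)
        assert (w.start_day, w.end_day) == (3, 9)

    def test_discontinuation_window(self):
        w = sp.build_window("S", make_rule("discontinuation"), EXPOSED,
                            days(*range(1, 11)), days(3, 4, 5, 6), discharge_day=12)
        assert (w.start_day, w.end_day) == (7, 10)

    def test_vka_on_discharge_day_only_is_dropped(self):
        w = sp.build_window("S", make_rule("initiation"), NONEXPOSED,
                            days(10), days(), discharge_day=10)
        assert w.exposure_status == NOT_APPLICABLE
        assert w.start_day is None and w.end_day is None

    def test_only_first_co_administration_run_counts(self):
        # runs 2-4 and 6-7: window closes offset days after day 4
        w = sp.build_window("S", make_rule("initiation"), EXPOSED,
                            days(*range(1, 9)), days(2, 3, 4, 6, 7), discharge_day=9)
        assert (w.start_day, w.end_day) == (3, 8)

    def test_truncation_at_discharge(self):
        w = sp.build_window("S", make_rule("initiation"), EXPOSED,
                            days(*range(1, 11)), days(3, 4, 5, 6), discharge_day=8)
        assert (w.start_day, w.end_day) == (4, 8)

    @pytest.mark.parametrize("offset_small,offset_big", [(1, 4), (0, 2), (2, 6)])
    def test_shrinking_offset_never_enlarges_windows(self, offset_small, offset_big):
        cfg_s = AnalysisConfig(offset_lag_days=offset_small)
        cfg_b = AnalysisConfig(offset_lag_days=offset_big)
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = np.sort(rng.choice(np.arange(1, 15), size=rng.integers(1, 8), replace=False))
            d = np.sort(rng.choice(np.arange(1, 15), size=rng.integers(0, 6), replace=False))
            discharge = int(rng.integers(v[-1], 20))
            for phase in ("initiation", "discontinuation"):
                rule = make_rule(phase)
                status = sp.classify_exposure(v, d, phase)
                ws = sp.build_window("S", rule, status, v, d, discharge, cfg_s)
                wb = sp.build_window("S", rule, status, v, d, discharge, cfg_b)
                if ws.exposure_status != NOT_APPLICABLE:
                    assert wb.exposure_status != NOT_APPLICABLE
                    assert ws.start_day == wb.start_day
                    assert ws.end_day <= wb.end_day
                # bounds never exceed the stay span
                for w in (ws, wb):
                    if w.exposure_status != NOT_APPLICABLE:
                        assert 1 <= w.start_day and w.end_day <= discharge

    def test_first_run_end(self):
        assert _first_run_end(days(2, 3, 4, 6, 7)) == 4
        assert _first_run_end(days(5)) == 5
        assert _first_run_end(days(1, 2, 3)) == 3


class TestDetectOutcome:
    def win(self, start=4, end=10):
        return sp.ObservationWindow("S", "R", EXPOSED, start, end)

    def test_threshold_inclusive_high(self):
        assert sp.detect_outcome(self.win(), days(7), np.array([5.0]), "INR_GE_HIGH")

    def test_out_of_window_ignored(self):
        assert not sp.detect_outcome(self.win(), days(3), np.array([6.2]), "INR_GE_HIGH")

    def test_low_outcome_requires_crossing(self):
        assert not sp.detect_outcome(self.win(), days(5, 6), np.array([2.1, 2.9]), "INR_LE_LOW")
        assert sp.detect_outcome(self.win(), days(5), np.array([1.5]), "INR_LE_LOW")

    def test_not_applicable_window_rejected(self):
        w = sp.ObservationWindow("S", "R", NOT_APPLICABLE)
        with pytest.raises(ValueError):
            sp.detect_outcome(w, days(5), np.array([2.0]), "INR_GE_HIGH")


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_table(subcohort, rule, config=sp.DEFAULT_CONFIG):
    """Re-derive the rule's 2x2 table from raw records, plain Python only."""
    a = b = c = d = 0
    for stay in subcohort.stays.itertuples():
        sid = stay.stay_id
        rows = subcohort.administrations
        vka = sorted({
            int(r.day) for r in rows[rows.stay_id == sid].itertuples()
            if r.atc_code.startswith(config.vka_atc_prefix)
        })
        if rule.drug.match_mode == "prefix":
            match = lambda code: any(code.startswith(p) for p in rule.drug.atc_codes)
        else:
            match = lambda code: code in rule.drug.atc_codes
        drug = sorted({
            int(r.day) for r in rows[rows.stay_id == sid].itertuples() if match(r.atc_code)
        })
        if not vka:
            continue
        co = sorted(set(vka) & set(drug))
        exposed = bool(co)
        if rule.phase == "discontinuation" and exposed:
            exposed = max(drug) < max(vka)
        onset, offset = config.onset_lag_days, config.offset_lag_days
        if exposed and rule.phase == "initiation":
            run_end = co[0]
            while run_end + 1 in co:
                run_end += 1
            start, end = co[0] + onset, min(run_end + offset, stay.discharge_day)
        elif exposed:
            start = max(drug) + onset
            end = min(max(drug) + offset, max(vka) + offset, stay.discharge_day)
        else:
            start, end = vka[0] + onset, min(vka[-1] + offset, stay.discharge_day)
        if start > end:
            continue
        labs = subcohort.labs
        outcome = False
        for r in labs[(labs.stay_id == sid) & (labs.analyte == "INR")].itertuples():
            if start <= int(r.day) <= end:
                if rule.expected_outcome == "INR_GE_HIGH" and r.value >= config.inr_high_threshold:
                    outcome = True
                if rule.expected_outcome == "INR_LE_LOW" and r.value <= config.inr_low_threshold:
                    outcome = True
        if exposed and outcome:
            a += 1
        elif exposed:
            b += 1
        elif outcome:
            c += 1
        else:
            d += 1
    return a, b, c, d


class TestAssembleTable:
    def test_fixture_tables_and_exposed_counts(self, fixture_cohort, included_fixture):
        sub, _ = included_fixture
        for rule in fixture_cohort.rules:
            table, n = sp.assemble_table(sub, rule)
            assert (table.a, table.b, table.c, table.d) == fixture_cohort.expected_tables[rule.phase]
            assert n == table.a + table.b

    def test_cell_total_equals_applicable_stays(self, fixture_cohort, included_fixture):
        sub, _ = included_fixture
        for rule in fixture_cohort.rules:
            table, _, windows = sp.assemble_table(sub, rule, return_windows=True)
            n_applicable = sum(1 for w in windows if w[2] != NOT_APPLICABLE)
            assert table.total == n_applicable

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_small_cohorts(self, seed):
        spec = sp.DrugSpec(
            label="drugX", atc_code="N02AX02", direction="potentiates_vka",
            exposure_prevalence=0.5, co_administration_probability=0.7,
            true_log_or_initiation=0.7, true_log_or_discontinuation=-0.7,
        )
        config = sp.SimulationConfig(n_stays=20, seed=seed, drug_specs=[spec],
                                     baseline_outcome_rate_high=0.3,
                                     baseline_outcome_rate_low=0.3)
        cohort, _ = sp.simulate_cohort(config)
        sub, _ = sp.apply_inclusion_criteria(cohort)
        for phase in ("initiation", "discontinuation"):
            for outcome in ("INR_GE_HIGH", "INR_LE_LOW"):
                rule = make_rule(phase, outcome)
                table, _ = sp.assemble_table(sub, rule)
                assert (table.a, table.b, table.c, table.d) == brute_force_table(sub, rule)

    def test_prefix_matching_agrees_with_oracle(self, fixture_cohort, included_fixture):
        sub, _ = included_fixture
        rule = make_rule("initiation", codes=("N02AX",), match_mode="prefix")
        table, _ = sp.assemble_table(sub, rule)
        assert (table.a, table.b, table.c, table.d) == brute_force_table(sub, rule)
        assert table.n_exposed == 3  # prefix covers the exact tramadol code

    def test_order_invariance(self, fixture_cohort, included_fixture):
        sub, _ = included_fixture
        rng = np.random.default_rng(3)
        shuffled = sp.Cohort(
            sub.stays.sample(frac=1, random_state=1).reset_index(drop=True),
            sub.administrations.sample(frac=1, random_state=2).reset_index(drop=True),
            sub.labs.sample(frac=1, random_state=3).reset_index(drop=True),
        )
        for rule in fixture_cohort.rules:
            t1, _ = sp.assemble_table(sub, rule)
            t2, _ = sp.assemble_table(shuffled, rule)
            assert (t1.a, t1.b, t1.c, t1.d) == (t2.a, t2.b, t2.c, t2.d)

    def test_golden_windows(self, fixture_cohort, included_fixture):
        sub, _ = included_fixture
        for rule in fixture_cohort.rules:
            _, _, windows = sp.assemble_table(sub, rule, return_windows=True)
            for sid, _, status, start, end, outcome in windows:
                assert (status, start, end, outcome) == fixture_cohort.expected_windows[
                    (sid, rule.phase)
                ]
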