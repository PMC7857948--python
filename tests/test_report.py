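"""Alert decisions, report rendering, end-to-end pipeline and CLI."""

import json

import pytest
from click.testing import CliRunner
from hypothesis import given, settings
from hypothesis import strategies as st

import spcddi as sp
from spcddi.cli import main as cli_main
from spcddi.estimation import FISHER, STEPWISE, ORResult, RuleEstimate
from spcddi.exposure import ContingencyTable
from spcddi.report import (
    INSUFFICIENT,
    NO_ASSOCIATION,
    PROTECTIVE,
    RISK,
    classify_rule,
    summarize_decisions,
)


def estimate(n_exposed=50, unadj=None, adj=None, step=None, table=None):
    status = "estimated" if n_exposed >= 3 else "insufficient_data"
    return RuleEstimate(
        rule_id="drug::initiation::INR_GE_HIGH",
        n_exposed=n_exposed,
        table=table or ContingencyTable(5, n_exposed - 5 if n_exposed >= 5 else 0, 20, 200),
        status=status,
        or_unadjusted=unadj, or_adjusted=adj, or_stepwise=step,
    )


def orr(point, lo, hi, method=STEPWISE, computable=True):
    return ORResult(method, point=point, lower95=lo, upper95=hi, computable=computable)


class TestClassify:
    def test_insufficient_data_keeps_alert_on(self):
        d = classify_rule(estimate(n_exposed=2))
        assert d.classification == INSUFFICIENT and d.alert_active

    def test_protective_or_deactivates(self):
        d = classify_rule(estimate(step=orr(0.63, 0.47, 0.82), unadj=orr(0.65, 0.48, 0.86, FISHER)))
        assert d.classification == PROTECTIVE and not d.alert_active
        assert d.basis == "stepwise"

    def test_interval_crossing_one_is_not_significant(self):
        d = classify_rule(estimate(step=orr(0.83, 0.67, 1.02), unadj=orr(0.83, 0.67, 1.02, FISHER)))
        assert d.classification == NO_ASSOCIATION

    def test_risk_keeps_alert_on(self):
        d = classify_rule(estimate(step=orr(2.4, 1.2, 4.8), unadj=orr(2.2, 1.1, 4.4, FISHER)))
        assert d.classification == RISK and d.alert_active

    def test_fallback_to_unadjusted_when_basis_not_computable(self):
        d = classify_rule(
            estimate(step=ORResult(STEPWISE, computable=False),
                     unadj=orr(0.4, 0.2, 0.8, FISHER))
        )
        assert d.classification == PROTECTIVE and d.basis == "unadjusted"
        assert "fell back" in d.notes

    def test_all_noncomputable_is_nonsignificant_with_warning(self):
        d = classify_rule(
            estimate(step=ORResult(STEPWISE, computable=False),
                     unadj=ORResult(FISHER, computable=False))
        )
        assert d.classification == NO_ASSOCIATION
        assert "no computable" in d.notes

    def test_nonsignificant_alert_policy_configurable(self):
        e = estimate(step=orr(0.9, 0.6, 1.3), unadj=orr(0.9, 0.6, 1.3, FISHER))
        off = classify_rule(e, sp.AnalysisConfig(deactivate_nonsignificant=True))
        on = classify_rule(e, sp.AnalysisConfig(deactivate_nonsignificant=False))
        assert not off.alert_active and on.alert_active

    @given(
        point=st.floats(0.05, 20),
        width=st.floats(1.01, 5),
        n_exposed=st.integers(0, 200),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_partition_and_deactivation_soundness(self, point, width, n_exposed):
        e = estimate(n_exposed=n_exposed,
                     step=orr(point, point / width, point * width),
                     unadj=orr(point, point / width, point * width, FISHER))
        d = classify_rule(e)
        assert d.classification in (INSUFFICIENT, NO_ASSOCIATION, PROTECTIVE, RISK)
        if d.classification == RISK:
            assert d.alert_active  # a significant risk is never deactivated
        summary = summarize_decisions([d])
        assert summary["total"] == 1
        assert sum(summary[c] for c in (INSUFFICIENT, NO_ASSOCIATION, PROTECTIVE, RISK)) == 1


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory):
    """Fixture cohort + single-drug rulebook written to disk."""
    tmp = tmp_path_factory.mktemp("pipeline")
    fx = sp.make_fixture_cohort()
    paths = [tmp / "stays.csv", tmp / "administrations.csv", tmp / "labs.csv"]
    sp.write_cohort(fx.cohort, *paths)
    rb = tmp / "rulebook.csv"
    sp.write_rulebook(fx.rulebook, rb)
    return [str(p) for p in paths] + [str(rb)]


class TestPipeline:
    def test_end_to_end_counts(self, pipeline_inputs, tmp_path):
        result = sp.run_pipeline(*pipeline_inputs, out_dir=tmp_path)
        counts = result.stage_counts
        assert counts["stays_total"] == 8 and counts["stays_included"] == 6
        assert counts["rules_expanded"] == 2
        assert counts["rules_estimated"] == 1 and counts["rules_insufficient"] == 1
        for name in ("report.md", "report.json", "decisions.csv"):
            assert (tmp_path / name).exists()

    def test_rerun_is_deterministic(self, pipeline_inputs, tmp_path):
        r1 = sp.run_pipeline(*pipeline_inputs, out_dir=tmp_path / "a")
        r2 = sp.run_pipeline(*pipeline_inputs, out_dir=tmp_path / "b")
        j1 = (tmp_path / "a" / "report.json").read_text()
        j2 = (tmp_path / "b" / "report.json").read_text()
        assert j1 == j2
        assert r1.stage_counts == r2.stage_counts

    def test_wider_alpha_weakly_reduces_nonsignificant(self, small_sim, tmp_path):
        _, cohort, _ = small_sim
        paths = [tmp_path / "s.csv", tmp_path / "a.csv", tmp_path / "l.csv"]
        sp.write_cohort(cohort, *paths)
        rb = tmp_path / "rb.csv"
        sp.write_rulebook(
            [sp.DrugEntry(label="drugX", direction="potentiates_vka",
                          atc_codes=frozenset({"N02AX02"}))], rb
        )
        res = {}
        for alpha in (0.05, 0.10):
            cfg = sp.AnalysisConfig(alpha=alpha)
            out = sp.run_pipeline(*paths, rb, cfg, tmp_path / f"out{alpha}")
            res[alpha] = sum(
                d.classification == NO_ASSOCIATION for d in out.decisions
            )
        assert res[0.10] <= res[0.05]

    def test_report_lists_only_significant_rules_in_tables(self, small_sim, tmp_path):
        _, cohort, _ = small_sim
        sub, _ = sp.apply_inclusion_criteria(cohort)
        rules = sp.expand_rules(
            [sp.DrugEntry(label="drugX", direction="potentiates_vka",
                          atc_codes=frozenset({"N02AX02"}))]
        )
        profiles = sp.build_profiles(sub)
        estimates = sp.estimate_all_rules(sub, rules, profiles)
        decisions = [classify_rule(e) for e in estimates]
        report = sp.render_report(decisions, estimates, rules, sp.describe_cohort(sub), tmp_path)
        md = (tmp_path / "report.md").read_text()
        sections = md.split("## Drug discontinuation")
        by_phase = {"initiation": sections[0], "discontinuation": sections[1]}
        for d in decisions:
            drug, phase, _ = d.rule_id.split("::")
            in_table = d.classification in (PROTECTIVE, RISK)
            # the summary always counts the rule; the main table lists it
            # only when the rule has a significant OR
            assert (f"| {drug} |" in by_phase[phase]) == in_table
        assert report["summary"]["total"] == len(decisions)

    def test_empty_decision_list_renders(self, tmp_path):
        report = sp.render_report([], [], [], None, tmp_path)
        assert report["summary"]["total"] == 0
        assert (tmp_path / "report.md").exists()


class TestCli:
    def test_simulate_analyze_report_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--seed", "3", "--n-stays", "120",
                                     "--out-dir", str(sim_dir)])
        assert r.exit_code == 0, r.output
        rb = tmp_path / "rulebook.csv"
        r = runner.invoke(cli_main, ["rulebook", "--out", str(rb)])
        assert r.exit_code == 0
        out_dir = tmp_path / "out"
        r = runner.invoke(cli_main, [
            "analyze",
            "--stays", str(sim_dir / "stays.csv"),
            "--administrations", str(sim_dir / "administrations.csv"),
            "--labs", str(sim_dir / "labs.csv"),
            "--rulebook", str(rb),
            "--out-dir", str(out_dir),
        ])
        assert r.exit_code == 0, r.output
        counts = json.loads(r.output)
        assert counts["rules_expanded"] == 282
        r = runner.invoke(cli_main, ["report", "--report-json", str(out_dir / "report.json")])
        assert r.exit_code == 0
        assert json.loads(r.output)["total"] == 282
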