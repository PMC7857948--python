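"""Alert activation decisions and Tables-style reporting.

This is the decision layer of a statistically prioritized and
contextualized CDSS (SPC-CDSS): each DDI rule's empirical evidence is
classified from its chosen odds-ratio tier, and the rule's alert is kept
active or deactivated accordingly.

Classification (on the basis OR's 95% confidence limits):

* ``insufficient_data`` — fewer exposed stays than the configured minimum;
  statistical filtering is ignored and the alert stays ON;
* ``significant_risk`` — lower limit > 1; alert stays ON;
* ``significant_protective`` — upper limit < 1; alert turned OFF;
* ``no_significant_association`` — otherwise; alert OFF by default
  (configurable: a conservative site can keep unresolved alerts on).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import (
    Cohort,
    CohortSummary,
    apply_inclusion_criteria,
    describe_cohort,
    read_cohort,
)
from .config import DEFAULT_CONFIG, AnalysisConfig
from .covariates import build_profiles
from .estimation import ORResult, RuleEstimate, estimate_all_rules
from .rulebook import DDIRule, curate_rulebook, expand_rules, load_rulebook

logger = logging.getLogger("spcddi")

INSUFFICIENT = "insufficient_data"
NO_ASSOCIATION = "no_significant_association"
PROTECTIVE = "significant_protective"
RISK = "significant_risk"
CLASSIFICATIONS = (INSUFFICIENT, NO_ASSOCIATION, PROTECTIVE, RISK)


@dataclass(frozen=True)
class RuleDecision:
    rule_id: str
    n_exposed: int
    classification: str
    alert_active: bool
    basis: str  # which OR tier drove the classification
    notes: str = ""


def _pick_basis(estimate: RuleEstimate, basis: str) -> tuple[ORResult | None, str, str]:
    """Basis ORResult with fallback to the unadjusted tier when noncomputable."""
    by_name = {
        "unadjusted": estimate.or_unadjusted,
        "adjusted": estimate.or_adjusted,
        "stepwise": estimate.or_stepwise,
    }
    chosen = by_name[basis]
    if chosen is not None and chosen.computable:
        return chosen, basis, ""
    fallback = by_name["unadjusted"]
    if fallback is not None and fallback.computable:
        return fallback, "unadjusted", f"{basis} OR not computable; fell back to unadjusted"
    return None, basis, "no computable OR in any tier"


def classify_rule(
    estimate: RuleEstimate,
    config: AnalysisConfig = DEFAULT_CONFIG,
    basis: str | None = None,
) -> RuleDecision:
    """Classify one rule's evidence and decide alert activation.

    Alerts stay active for ``significant_risk`` and for
    ``insufficient_data`` (no statistical filtering on thin evidence);
    they are deactivated for ``significant_protective`` and — by default —
    for ``no_significant_association``.
    """
    basis = basis or config.basis
    if estimate.status == INSUFFICIENT:
        return RuleDecision(
            rule_id=estimate.rule_id, n_exposed=estimate.n_exposed,
            classification=INSUFFICIENT, alert_active=True, basis="none",
            notes="too few exposed stays; statistical filtering ignored",
        )
    result, used, note = _pick_basis(estimate, basis)
    if result is None:
        return RuleDecision(
            rule_id=estimate.rule_id, n_exposed=estimate.n_exposed,
            classification=NO_ASSOCIATION,
            alert_active=not config.deactivate_nonsignificant,
            basis=used, notes=note,
        )
    if result.significant_risk:
        cls, active = RISK, True
    elif result.significant_protective:
        cls, active = PROTECTIVE, False
    else:
        cls, active = NO_ASSOCIATION, not config.deactivate_nonsignificant
    return RuleDecision(
        rule_id=estimate.rule_id, n_exposed=estimate.n_exposed,
        classification=cls, alert_active=active, basis=used, notes=note,
    )


def summarize_decisions(decisions: list[RuleDecision]) -> dict:
    counts = {cls: 0 for cls in CLASSIFICATIONS}
    for d in decisions:
        counts[d.classification] += 1
    counts["total"] = len(decisions)
    counts["alerts_active"] = sum(d.alert_active for d in decisions)
    counts["alerts_deactivated"] = sum(not d.alert_active for d in decisions)
    return counts


_OUTCOME_LABEL = {"INR_GE_HIGH": "INR>=5", "INR_LE_LOW": "INR<=1.5"}


def _or_cell(result: ORResult | None) -> str:
    if result is None:
        return ""
    return result.format()


def render_report(
    decisions: list[RuleDecision],
    estimates: list[RuleEstimate],
    rules: list[DDIRule],
    descriptives: CohortSummary | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Render per-phase result tables plus a machine-readable twin.

    The main markdown tables list, per phase, the rules with at least one
    significant OR in any tier, sorted by therapeutic group then drug, with
    columns Drug | Outcome | n | OR (95% CLs) | Adjusted OR | Stepwise OR;
    noncomputable limits are footnoted. All rules appear in the summary
    counts and in the JSON/CSV twins. Returns the report as a dict; writes
    ``report.md``, ``report.json`` and ``decisions.csv`` when ``out_dir``
    is given.
    """
    by_id = {r.rule_id: r for r in rules}
    est_by_id = {e.rule_id: e for e in estimates}
    summary = summarize_decisions(decisions)

    rows = []
    for d in decisions:
        rule = by_id[d.rule_id]
        e = est_by_id[d.rule_id]
        rows.append(
            {
                "rule_id": d.rule_id,
                "drug": rule.drug.label,
                "group": rule.drug.group,
                "phase": rule.phase,
                "outcome": _OUTCOME_LABEL[rule.expected_outcome],
                "n": d.n_exposed,
                "or_unadjusted": _or_cell(e.or_unadjusted),
                "or_adjusted": _or_cell(e.or_adjusted),
                "or_stepwise": _or_cell(e.or_stepwise),
                "p_outcome_exposed": e.p_outcome_exposed,
                "p_outcome_nonexposed": e.p_outcome_nonexposed,
                "classification": d.classification,
                "alert_active": d.alert_active,
                "basis": d.basis,
            }
        )
    frame = pd.DataFrame(rows)

    lines = ["# Empirical DDI-rule evaluation", ""]
    if descriptives is not None and descriptives.n_stays:
        lines += [
            f"Analyzed stays: {descriptives.n_stays} "
            f"(mean age {descriptives.age_mean} y, "
            f"median LOS {descriptives.los_median:g} d)",
            "",
        ]
    lines += ["## Summary", ""]
    for key, val in summary.items():
        lines.append(f"- {key}: {val}")
    footnote_needed = False
    for phase, title in (("initiation", "Drug initiation"), ("discontinuation", "Drug discontinuation")):
        lines += ["", f"## {title}: rules with at least one significant OR", ""]
        if frame.empty:
            lines.append("(no rules)")
            continue
        sub = frame[(frame.phase == phase) & (frame.classification.isin((PROTECTIVE, RISK)))]
        sub = sub.sort_values(["group", "drug"])
        if sub.empty:
            lines.append("(none)")
            continue
        lines.append("| Drug | Outcome | n | OR (95% CLs) | Adjusted OR | Stepwise OR |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in sub.iterrows():
            cells = [r.or_unadjusted, r.or_adjusted, r.or_stepwise]
            cells = [c.replace("(NC)", "^d") for c in cells]
            footnote_needed |= any("^d" in c for c in cells)
            lines.append(
                f"| {r.drug} | {r.outcome} | {r.n} | {cells[0]} | {cells[1]} | {cells[2]} |"
            )
    if footnote_needed:
        lines += ["", "^d: the 95% confidence limits were not computable."]
    markdown = "\n".join(lines) + "\n"

    report = {
        "summary": summary,
        "rules": rows,
        "descriptives": descriptives.to_dict() if descriptives is not None else None,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(markdown, encoding="utf-8")
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str), encoding="utf-8")
        if not frame.empty:
            frame.to_csv(out / "decisions.csv", index=False)
        else:
            (out / "decisions.csv").write_text("", encoding="utf-8")
    report["markdown"] = markdown
    return report


@dataclass
class PipelineResult:
    subcohort: Cohort
    summary: CohortSummary
    rules: list[DDIRule]
    estimates: list[RuleEstimate]
    decisions: list[RuleDecision]
    report: dict
    stage_counts: dict


def run_pipeline(
    stays_path: str | Path,
    administrations_path: str | Path,
    labs_path: str | Path,
    rulebook_path: str | Path,
    config: AnalysisConfig = DEFAULT_CONFIG,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """End-to-end deterministic run: read, include, expand, estimate, decide.

    Stage counts (stays included, rules expanded/estimated/deactivated) are
    logged and returned for audit.
    """
    cohort = read_cohort(
        stays_path, administrations_path, labs_path, delimiter=config.delimiter
    )
    logger.info("read cohort: %d stays", cohort.n_stays)
    subcohort, inclusion = apply_inclusion_criteria(cohort, config)
    logger.info(
        "inclusion: %d of %d stays retained (%.2f%%)",
        inclusion.retained, inclusion.total, inclusion.retained_pct,
    )
    entries = load_rulebook(rulebook_path)
    curated, curation = curate_rulebook(entries)
    rules = expand_rules(curated, config)
    logger.info(
        "rulebook: %d entries -> %d curated -> %d rules",
        curation.n_input, curation.n_output, len(rules),
    )
    profiles = build_profiles(subcohort)
    estimates = estimate_all_rules(subcohort, rules, profiles, config)
    decisions = [classify_rule(e, config) for e in estimates]
    summary = describe_cohort(subcohort, config)
    report = render_report(decisions, estimates, rules, summary, out_dir)
    stage_counts = {
        "stays_total": inclusion.total,
        "stays_included": inclusion.retained,
        "included_pct": inclusion.retained_pct,
        "rulebook_entries": curation.n_input,
        "rulebook_curated": curation.n_output,
        "rules_expanded": len(rules),
        "rules_estimated": sum(e.status == "estimated" for e in estimates),
        "rules_insufficient": sum(e.status == INSUFFICIENT for e in estimates),
        "alerts_deactivated": report["summary"]["alerts_deactivated"],
    }
    logger.info("pipeline complete: %s", stage_counts)
    return PipelineResult(
        subcohort=subcohort, summary=summary, rules=rules, estimates=estimates,
        decisions=decisions, report=report, stage_counts=stage_counts,
    )


def estimates_frame(estimates: list[RuleEstimate], rules: list[DDIRule]) -> pd.DataFrame:
    """Per-rule estimates as a tidy DataFrame (one row per rule)."""
    by_id = {r.rule_id: r for r in rules}
    rows = []
    for e in estimates:
        rule = by_id[e.rule_id]
        row = {
            "rule_id": e.rule_id,
            "drug": rule.drug.label,
            "phase": rule.phase,
            "outcome": _OUTCOME_LABEL[rule.expected_outcome],
            "n_exposed": e.n_exposed,
            "a": e.table.a, "b": e.table.b, "c": e.table.c, "d": e.table.d,
            "status": e.status,
        }
        for name, res in (
            ("unadjusted", e.or_unadjusted),
            ("adjusted", e.or_adjusted),
            ("stepwise", e.or_stepwise),
        ):
            row[f"or_{name}"] = res.point if res is not None else float("nan")
            row[f"or_{name}_low"] = res.lower95 if res is not None else float("nan")
            row[f"or_{name}_high"] = res.upper95 if res is not None else float("nan")
            row[f"or_{name}_computable"] = res.computable if res is not None else False
        rows.append(row)
    return pd.DataFrame(rows)
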