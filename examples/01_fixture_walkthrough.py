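"""Walk through the window logic on a tiny hand-checkable cohort.

Builds the 8-stay fixture cohort (one interacting drug, tramadol, against a
fluindione VKA episode), applies the inclusion criteria, and prints each
stay's exposure status, observation window and detected INR excursion for
the initiation and discontinuation rules, followed by the 2x2 tables and
the estimated odds ratios.
"""

import spcddi as sp

fx = sp.make_fixture_cohort()
sub, counts = sp.apply_inclusion_criteria(fx.cohort)
print(f"stays: {counts.total} total, {counts.retained} included "
      f"({counts.retained_pct}%) — a stay needs >=1 INR result and >=1 VKA day")

profiles = sp.build_profiles(sub)
for rule in fx.rules:
    table, n_exposed, windows = sp.assemble_table(sub, rule, return_windows=True)
    print(f"\nrule: {rule.rule_id}")
    for sid, _, status, start, end, outcome in windows:
        span = f"days {start}-{end}" if start is not None else "no observable window"
        print(f"  {sid}: {status:>14}  {span:>22}  outcome={outcome}")
    print(f"  table a,b,c,d = {table.a},{table.b},{table.c},{table.d}  "
          f"(n exposed = {n_exposed})")

print("\nthree-tier odds ratios (point and 95% confidence limits):")
for est in sp.estimate_all_rules(sub, fx.rules, profiles):
    if est.status == "insufficient_data":
        print(f"  {est.rule_id}: fewer than 3 exposed stays -> ORs not computed")
        continue
    print(f"  {est.rule_id}:")
    for r in (est.or_unadjusted, est.or_adjusted, est.or_stepwise):
        print(f"    {r.method:20s} {r.format()}")
# An infinite unadjusted OR here is expected: no nonexposed stay had the
# outcome (c = 0), so the conditional MLE diverges and is flagged.
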