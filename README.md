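# spcddi

Empirical filtering of vitamin-K-antagonist (VKA) drug–drug-interaction
alerts from longitudinal inpatient EHR data.

## The problem

Clinical decision support systems embedded in computerized order entry fire
a pop-up whenever a prescription matches a drug–drug-interaction (DDI) rule.
For VKAs — anticoagulants with a narrow therapeutic window monitored through
the INR — the literature-derived rule list is long, and alerting on all of
it produces alert fatigue: clinicians override nearly everything, including
the warnings that matter. A *statistically prioritized and contextualized*
CDSS (SPC-CDSS) instead estimates, from the hospital's own historical EHR
data, the probability that each rule's predicted outcome actually follows
its trigger, and deactivates rules whose empirical risk is low — while
keeping every rule with too little local evidence.

`spcddi` implements that analysis end to end for pharmacoepidemiologists
and CDSS engineers:

1. **EHR model** — three delimited-text tables (stays, daily drug
   administrations by ATC code, laboratory results), validated against
   referential and range invariants; stays are analyzed when they have at
   least one INR result and at least one VKA (ATC `B01AA*`) administration
   day.
2. **Rulebook** — literature-derived interacting drugs, each potentiating
   (expected INR ≥ 5) or inhibiting (expected INR ≤ 1.5) the VKA; curation
   drops entries without ATC terms and merges entries sharing an ATC code,
   and every curated entry expands into an initiation rule and a
   discontinuation rule with the reverse expected outcome.
3. **Exposure engine** — per (stay, rule) exposure status and observation
   window. An exposed initiation window opens the day after the first
   co-administration day and closes 4 days after the first uninterrupted
   co-administration run ends; a nonexposed window tracks the VKA episode
   itself; windows truncate at discharge. The window is searched for the
   rule's INR excursion (thresholds inclusive).
4. **Estimation** — for each rule with ≥ 3 exposed stays, a three-tier
   odds-ratio cascade over the 2×2 exposure-by-outcome table (*a, b, c, d*):
   - *unadjusted*: the conditional maximum-likelihood OR of the noncentral
     hypergeometric model, with exact confidence limits that invert the
     tail probabilities at α/2 (the estimator behind Fisher's exact test);
   - *adjusted*: exp(β̂) for the exposure term of a multivariable logistic
     regression on exposure plus seven categorized covariates (age,
     albumin, prealbumin, creatinine, ASAT/ALAT, TSH, NT-proBNP — surrogate
     markers for age, malnutrition, kidney/liver failure, dysthyroidism and
     heart failure), Wald limits; missing labs are imputed with the normal
     (reference) category;
   - *stepwise*: the same model after bidirectional AIC selection with the
     exposure term locked in.
5. **Decision layer** — each rule is classified from its basis OR's 95%
   confidence limits (`significant_risk` if the lower limit exceeds 1,
   `significant_protective` if the upper limit is below 1, otherwise no
   significant association; `insufficient_data` below 3 exposed stays) and
   its alert is kept active or deactivated accordingly. Alerts are never
   deactivated on thin evidence.
6. **Synthetic EHR generator** — a seeded simulator producing cohorts with
   the demographic structure of an elderly VKA inpatient population and
   INR-excursion odds that follow a configurable logistic model, with
   serialized ground truth, so every estimator in the pipeline can be
   validated by parameter recovery.

## Worked example

`examples/02_injected_effect_recovery.py` simulates 2000 VKA stays in which
a companion drug doubles the odds of an INR ≥ 5 excursion while
co-administered (true OR = 2), then runs the estimation cascade:

```
simulated 2000 stays, 2000 included; 624 exposed to drugX while on a VKA

drugX::initiation::INR_GE_HIGH  (true OR = 2.0)
  2x2 table: a=101 b=523 c=144 d=1232
  fisher_unadjusted    1.65 (1.24, 2.19)
  logistic_adjusted    1.64 (1.25, 2.16)
  logistic_stepwise    1.65 (1.26, 2.17)
  decision: significant_risk -> alert ACTIVE
```

All three tiers bracket the injected OR of 2 within their 95% confidence
limits, and the decision layer keeps the alert active because the lower
confidence limit exceeds 1. The other examples walk the window logic on a
hand-checkable 8-stay fixture (`01_fixture_walkthrough.py`) and run the full
282-rule reference rulebook end to end (`03_full_rulebook_pipeline.py`) —
there, rules for drugs never co-administered with a VKA come out
`insufficient_data` and keep their alerts, while drugs simulated with
protective effects are deactivated.

## Command line

```bash
spc-ddi simulate --seed 3 --n-stays 2000 --out-dir sim/
spc-ddi rulebook --out rulebook.csv
spc-ddi analyze --stays sim/stays.csv --administrations sim/administrations.csv \
                --labs sim/labs.csv --rulebook rulebook.csv --out-dir out/
spc-ddi report --report-json out/report.json
```

`analyze` writes `report.md` (per-phase tables of rules with at least one
significant OR, columns Drug | Outcome | n | OR (95% CLs) | Adjusted OR |
Stepwise OR), `report.json` and `decisions.csv`.

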