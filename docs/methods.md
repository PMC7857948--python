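# Methods

This note documents the statistical procedure implemented by `spcddi`, its
assumptions, the tunable parameters, the synthetic-data generator's design,
and the numerical choices made where the design was genuinely open.

## Study design

The unit of analysis is the inpatient *stay*, not the patient: an alert
filter is calibrated against solicitations of the CDSS inference engine,
so repeatedly hospitalized patients legitimately carry more weight, and no
within-patient correlation structure is modelled. Time is measured in whole
days with day 1 = admission; the source data are daily drug administrations,
so "administered together" means "on the same calendar day", and multiple
administrations of a drug within one day are indistinguishable.

A stay enters the analysis when it has at least one INR laboratory result
and at least one day with a VKA administration (any ATC code starting with
`B01AA`; several distinct VKA codes in one stay are pooled, since the
analysis treats VKAs as a class).

## Exposure and observation windows

Each DDI rule pairs one interacting drug with one expected INR excursion:
potentiation (INR ≥ `inr_high_threshold`, default 5.0, inclusive) or
inhibition (INR ≤ `inr_low_threshold`, default 1.5, inclusive). Initiation
rules carry the drug's own direction; discontinuation rules carry the
reverse (withdrawing a potentiator leaves the VKA under-dosed, and vice
versa).

Two lags shape every window: `onset_lag_days` (default 1 day — drug effects
on the INR are not instantaneous) and `offset_lag_days` (default 4 days of
residual action after discontinuation). The same two lags are applied to
every drug; pharmacokinetic heterogeneity across drugs is a documented
approximation, not modelled.

* **Exposed, initiation**: a stay is exposed when at least one day carries
  both the VKA and the drug. The window runs from (first co-administration
  day + onset) to (last day of the *first uninterrupted co-administration
  run* + offset), truncated at discharge. Only the first episode counts;
  re-initiations later in the stay are ignored (multi-episode handling is
  unspecified in the underlying design, and a single well-defined episode
  keeps the window interpretable).
* **Exposed, discontinuation**: additionally the drug's last administration
  must precede the VKA's last administration — the drug stopped while the
  VKA continued. The window runs from (drug's last day + onset) to (drug's
  last day + offset), capped by the VKA's own residual window and by
  discharge.
* **Nonexposed (either phase)**: the VKA episode's own window, (first VKA
  day + onset) to (last VKA day + offset), truncated at discharge. For
  discontinuation rules the nonexposed set deliberately includes stays
  where the drug was given but never discontinued; the comparison mirrors
  the initiation contrast.
* A window whose start exceeds its end (e.g. a VKA administered only on the
  discharge day) is dropped from that rule's table entirely.

The outcome is the *any-occurrence* binary indicator of an in-window INR
beyond the rule's threshold; excursions before the window start are
ignored, and there is no post-discharge follow-up because no data exist
after discharge.

## Estimation

Rules with fewer than `min_exposed_stays` (default 3) exposed stays are
flagged `insufficient_data` and no odds ratio is computed. Otherwise, over
the 2×2 table (a = exposed with outcome, b = exposed without, c = nonexposed
with, d = nonexposed without):

1. **Unadjusted OR** — the conditional MLE of the noncentral hypergeometric
   model with exact limits inverting the tail probabilities at α/2
   (`scipy.stats.contingency.odds_ratio`, the estimator reported by
   `fisher.test`-style implementations). This choice, rather than the
   cross-product Wald OR, handles zero cells gracefully: a = 0 yields point
   0 with a finite upper limit; b = 0 or c = 0 yields an infinite point
   estimate, which is reported but flagged non-computable for decisions.
   Tables with no outcome variation are non-computable.
2. **Adjusted OR** — exp of the exposure coefficient from a logistic
   regression of the outcome on exposure plus the seven categorized
   covariates, Wald limits. Constant (all-reference) dummy columns are
   dropped so the information matrix stays full rank; with no covariate
   variation at all the fit reduces to the exposure-only model, whose MLE
   equals ad/bc exactly (a property the tests verify to 1e-6).
3. **Stepwise OR** — bidirectional AIC-driven selection starting from the
   full model, moving whole covariate blocks (all dummies of one
   categorical variable together) and stopping when no single add/drop
   improves the AIC; the exposure term never leaves the model. The
   selection criterion and direction were open choices; AIC-based
   bidirectional selection is the common default and is deterministic.

**Separation and convergence.** A fit is flagged non-computable when the
exposure coefficient or its Wald standard error is non-finite or exceeds
`separation_bound` (default 15 on the log scale), or when the optimizer
fails to reach a zero score. Convergence is judged on the score vector
rather than on the optimizer's own flag: a quasi-separated *nuisance* dummy
(e.g. a sparse covariate class with no outcomes) drives its own coefficient
toward −∞ without ever affecting the exposure term, whose estimate and
standard error are stable; discarding the whole rule in that situation
would throw away a perfectly estimable exposure effect.

**Covariate categories** (reference first): age < 70 / 70–79 / ≥ 80 years;
albumin ≥ 30 / < 30 g/L; prealbumin ≥ 0.11 / 0.07–0.10 / < 0.07 g/L;
creatinine ≤ 15 / 16–24 / ≥ 25 mg/L; max(ASAT, ALAT) < 250 / ≥ 250 IU/L;
TSH 0.5–5 / outside mU/L; NT-proBNP < 450 / ≥ 450 pg/mL. The printed
integer-style class labels leave gaps for fractional values (creatinine
15.5, prealbumin 0.105); gaps are assigned to the middle class so the
labels stay exact for integer-valued data while the categorizer remains a
total function. "ASAT/ALAT ≥ 250 IU/L" is read as a level threshold on
either transaminase (the IU/L unit rules out a ratio reading). Each
covariate uses the stay's *first* measured value (approximating admission
status and deterministic; a `worst`-value selection is available). A
missing measurement is imputed with the reference category: in routine
care, an unmeasured parameter is most likely normal, so the data are
treated as not missing at random.

No multiple-testing correction is applied across rules: the decision layer
consumes per-rule 95% confidence limits at the configured α (default 0.05),
which is how an alert filter consumes them; a higher α deactivates fewer
alerts.

## Decision layer

The basis estimate defaults to the stepwise OR (the final model of the
cascade) and falls back to the unadjusted OR when non-computable.
Classification: `significant_risk` (lower limit > 1, alert stays active),
`significant_protective` (upper limit < 1, alert deactivated),
`no_significant_association` (deactivated by default; a conservative site
can flip `deactivate_nonsignificant`), `insufficient_data` (alert stays
active — statistical filtering is ignored when the learning database is too
small). Per-rule empirical conditional outcome probabilities
(a/(a+b), c/(c+d)) are exposed for sites preferring a probability-threshold
policy over CI-based classification.

## Synthetic cohort generator

The generator validates the pipeline; it does not model coagulation
physiology. Demographics are calibrated to an elderly VKA inpatient
population: age ~ Normal(75.9, 12²) clipped to [18, 105]; 58.2% women;
length of stay from a discretized lognormal with μ = ln 9 and σ fitted
numerically to the quartiles (6, 15), clipped to [3, 90] days; 4%
in-hospital mortality; a fluindione-dominant VKA mix (80.5% fluindione,
13.7% warfarin, 5.6% acenocoumarol). Each stay receives one VKA episode
spanning most of the stay and at least one INR measurement, so inclusion
retains every simulated stay.

Outcomes are generated *at the window level on the logistic scale*: per
stay, latent indicators for the high and low excursion are drawn from
logit P = β₀ + β_drug·exposed + Σ covariate effects, and when an indicator
fires, an INR beyond the relevant threshold is placed uniformly at random
on a day inside the stay's analytic window, computed with the same window
rules as the exposure engine; all other INR values lie strictly between the
thresholds. Injected log-ORs are therefore exact on the scale the
estimators work on, which makes recovery tests well-posed.

Two deliberate simplifications follow from that design:

* **At most one companion drug per stay.** With a single latent outcome per
  excursion type, the outcome day must fall inside *every* relevant rule's
  window. An exposed window is always nested in the VKA window that every
  nonexposed rule uses, so one companion drug guarantees exact consistency;
  two overlapping companion drugs with disjoint windows could not both
  agree with one latent outcome. Simulated cohorts therefore contain no
  cross-rule contamination from concomitant interacting drugs — a feature
  real data do have, and a known limitation of the analysis itself.
* **Covariate effects default to zero** (labs are still generated, with
  realistic per-analyte missingness, so the adjusted tier fits a genuine
  design matrix). Logistic ORs are non-collapsible: with prognostic
  covariates, the marginal OR the unadjusted tier estimates differs from
  the conditional OR injected into the model, and neither tier could be
  scored against a single truth. With zero covariate effects the two
  coincide and both tiers are scored against the same injected value.
  Nonzero effects are one config field away for users studying confounding.

Ground truth (per-drug injected log-ORs, realized exposure counts, per-stay
latent outcomes) is serialized alongside the cohort as `truth.json`.

## Problem sizes used by tests and the acceptance script

Parameter recovery uses 200 replicates of 2000-stay cohorts per injected OR
in {0.5, 1, 2, 3} (mean log-OR bias below 0.1, coverage within
[0.92, 0.98]); type-I calibration uses 63 cohorts of 1250 stays with 8 null
drugs each (504 rules, significance rate within [0.03, 0.07]); the Fisher
estimator is checked exhaustively against a grid-search likelihood oracle
on all 44,515 2×2 tables with total ≤ 30 and non-degenerate margins. The
acceptance script runs reduced replicate counts (40 per injected OR, 16
null cohorts) to report the same quantities quickly.

## Known limitations

Dose levels are not modelled; exposure is daily-grain binary. The outcome
is an INR excursion, a surrogate that neither implies nor is implied by a
clinical event. One onset and one residual lag serve all drugs. Outcomes
occurring before the window opens are ignored rather than censored.
Significant associations estimated this way are associational: indication
bias (drugs prescribed in particular clinical contexts) is expected, and
protective point estimates should not be read as pharmacological protection.
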