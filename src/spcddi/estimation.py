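"""Per-rule odds-ratio estimation: Fisher exact, adjusted, stepwise.

For every DDI rule with at least ``min_exposed_stays`` exposed stays, three
odds ratios for the rule's INR excursion are estimated over the full set of
included stays:

1. *unadjusted* — the conditional maximum-likelihood OR of the 2x2
   exposure-by-outcome table under the noncentral hypergeometric model,
   with exact confidence limits obtained by inverting the tail
   probabilities at ``alpha/2`` (the estimator reported by Fisher-exact-test
   implementations such as R's ``fisher.test``);
2. *adjusted* — ``exp`` of the exposure coefficient of a multivariable
   logistic regression on exposure plus the seven categorised covariates,
   with Wald confidence limits;
3. *stepwise* — the same model after bidirectional AIC-driven covariate
   selection with the exposure term forced to stay in the model.

Degenerate tables and separated fits are flagged rather than reported:
an OR result carries a ``computable`` flag and a note, mirroring the
"confidence limits not computable" footnotes of sparse-data tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import contingency

from .config import DEFAULT_CONFIG, AnalysisConfig
from .covariates import CATEGORIES, design_matrix
from .exposure import ContingencyTable, _CohortIndex, assemble_table

FISHER = "fisher_unadjusted"
ADJUSTED = "logistic_adjusted"
STEPWISE = "logistic_stepwise"


@dataclass(frozen=True)
class ORResult:
    """A point estimate with 95% confidence limits and computability flags."""

    method: str
    point: float = float("nan")
    lower95: float = float("nan")
    upper95: float = float("nan")
    computable: bool = True
    notes: str = ""

    @property
    def significant_protective(self) -> bool:
        return self.computable and self.upper95 < 1.0

    @property
    def significant_risk(self) -> bool:
        return self.computable and self.lower95 > 1.0

    def format(self, decimals: int = 2) -> str:
        """Render as ``point (lower, upper)`` with half-up rounding and
        trailing zeros trimmed, the convention of the result tables."""
        from ._util import round_half_up

        def fmt(v: float) -> str:
            if math.isinf(v):
                return "inf"
            return f"{round_half_up(v, decimals):g}"

        if not self.computable:
            return "NC" if math.isnan(self.point) else f"{fmt(self.point)} (NC)"
        return f"{fmt(self.point)} ({fmt(self.lower95)}, {fmt(self.upper95)})"


@dataclass
class RuleEstimate:
    """All estimation output for one rule."""

    rule_id: str
    n_exposed: int
    table: ContingencyTable
    status: str  # "estimated" | "insufficient_data"
    or_unadjusted: ORResult | None = None
    or_adjusted: ORResult | None = None
    or_stepwise: ORResult | None = None
    # empirical conditional outcome probabilities, for probability-threshold
    # filtering policies
    p_outcome_exposed: float = float("nan")
    p_outcome_nonexposed: float = float("nan")


def fisher_or(table: ContingencyTable, alpha: float = 0.05) -> ORResult:
    """Conditional-MLE odds ratio with exact confidence limits.

    A zero exposed-with-outcome cell yields point 0 with a finite upper
    limit; a zero ``b`` or ``c`` cell yields an infinite point estimate,
    flagged non-computable for downstream classification. Tables with no
    outcome variation (``a+c==0`` or ``b+d==0``) are non-computable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        return ORResult(FISHER, computable=False, notes="no outcome variation")
    if a + b == 0 or c + d == 0:
        return ORResult(FISHER, computable=False, notes="empty exposure arm")
    res = contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=1 - alpha)
    point = float(res.statistic)
    if math.isinf(point):
        return ORResult(
            FISHER, point=point, lower95=float(ci.low), upper95=float(ci.high),
            computable=False, notes="zero cell: point estimate infinite",
        )
    notes = "zero exposed-with-outcome cell" if a == 0 else ""
    return ORResult(
        FISHER, point=point, lower95=float(ci.low), upper95=float(ci.high), notes=notes
    )


def _wald_result(
    method: str, fit, alpha: float, separation_bound: float, notes: str = ""
) -> ORResult:
    beta = float(fit.params["exposed"])
    se = float(fit.bse["exposed"])
    # Convergence is judged on the score: a quasi-separated nuisance dummy
    # can keep the optimizer's own flag False for ever while the exposure
    # coefficient is at its (finite) maximum-likelihood value.
    retvals = getattr(fit, "mle_retvals", {})
    converged = bool(retvals.get("converged", True))
    score = retvals.get("score")
    if not converged and score is not None:
        converged = bool(np.max(np.abs(score)) < 1e-4)
    # Separation of the exposure itself: huge |beta| or an exploding Wald SE.
    if (
        not np.isfinite(beta)
        or not np.isfinite(se)
        or abs(beta) > separation_bound
        or se > separation_bound
        or not converged
    ):
        return ORResult(
            method, point=math.exp(beta) if np.isfinite(beta) else float("nan"),
            computable=False,
            notes=(notes + "; " if notes else "") + "separation or non-convergence detected",
        )
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return ORResult(
        method,
        point=math.exp(beta),
        lower95=math.exp(beta - z * se),
        upper95=math.exp(beta + z * se),
        notes=notes,
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        return model.fit(disp=0, maxiter=100, warn_convergence=False)


def _prepare_design(
    exposed: np.ndarray, covariate_dummies: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Full design: intercept + exposure + non-constant covariate dummies.

    Constant (zero-variance) dummy columns are dropped — e.g. when every
    stay sits at the reference level of a covariate — so the information
    matrix stays full-rank. Returns the design and the covariate blocks
    (one per covariate with at least one retained dummy)."""
    X = pd.DataFrame({"const": 1.0, "exposed": exposed.astype(float)},
                     index=covariate_dummies.index)
    blocks: list[str] = []
    for cov in CATEGORIES:
        kept = [
            col for col in covariate_dummies.columns
            if col.startswith(f"{cov}:") and covariate_dummies[col].nunique() > 1
        ]
        if kept:
            X[kept] = covariate_dummies[kept]
            blocks.append(cov)
    return X, blocks


def adjusted_or(
    outcome: np.ndarray,
    exposed: np.ndarray,
    covariate_dummies: pd.DataFrame,
    alpha: float = 0.05,
    separation_bound: float = 15.0,
) -> ORResult:
    """Adjusted OR from the full multivariable logistic model."""
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        return ORResult(ADJUSTED, computable=False, notes="constant outcome")
    if exposed.min() == exposed.max():
        return ORResult(ADJUSTED, computable=False, notes="constant exposure")
    X, _ = _prepare_design(np.asarray(exposed), covariate_dummies)
    try:
        fit = _fit_logit(y, X)
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        return ORResult(ADJUSTED, computable=False, notes=f"fit failed: {type(exc).__name__}")
    return _wald_result(ADJUSTED, fit, alpha, separation_bound)


def stepwise_or(
    outcome: np.ndarray,
    exposed: np.ndarray,
    covariate_dummies: pd.DataFrame,
    alpha: float = 0.05,
    separation_bound: float = 15.0,
) -> ORResult:
    """Stepwise OR: bidirectional AIC selection, exposure locked in.

    Starting from the full model, each step considers dropping any included
    covariate block or re-adding any dropped one (a block is the whole dummy
    set of one categorical covariate) and takes the move with the best AIC;
    selection stops when no move improves the AIC.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        return ORResult(STEPWISE, computable=False, notes="constant outcome")
    if exposed.min() == exposed.max():
        return ORResult(STEPWISE, computable=False, notes="constant exposure")
    X_full, blocks = _prepare_design(np.asarray(exposed), covariate_dummies)
    block_cols = {
        cov: [col for col in X_full.columns if col.startswith(f"{cov}:")] for cov in blocks
    }

    def fit_subset(included: frozenset) -> tuple:
        cols = ["const", "exposed"] + [c for cov in blocks if cov in included
                                       for c in block_cols[cov]]
        try:
            fit = _fit_logit(y, X_full[cols])
            return float(fit.aic), fit
        except Exception:
            return float("inf"), None

    included = frozenset(blocks)
    best_aic, best_fit = fit_subset(included)
    if best_fit is None:
        return ORResult(STEPWISE, computable=False, notes="full model fit failed")
    improved = True
    while improved:
        improved = False
        candidates = [included - {cov} for cov in included] + [
            included | {cov} for cov in blocks if cov not in included
        ]
        for cand in candidates:
            aic, fit = fit_subset(cand)
            if aic < best_aic - 1e-9 and fit is not None:
                best_aic, best_fit, included = aic, fit, cand
                improved = True
    kept = ",".join(sorted(included)) if included else "none"
    return _wald_result(STEPWISE, best_fit, alpha, separation_bound,
                        notes=f"covariates kept: {kept}")


def estimate_rule(
    rule,
    subcohort,
    profiles: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
    *,
    index: _CohortIndex | None = None,
    dummies: pd.DataFrame | None = None,
) -> RuleEstimate:
    """Assemble the rule's table and run the three-tier OR cascade."""
    idx = index if index is not None else _CohortIndex(subcohort, config)
    table, n_exposed, windows = assemble_table(
        subcohort, rule, config, index=idx, return_windows=True
    )
    if n_exposed < config.min_exposed_stays:
        return RuleEstimate(
            rule_id=rule.rule_id, n_exposed=n_exposed, table=table,
            status="insufficient_data",
        )
    frame = pd.DataFrame(
        [w for w in windows if w[2] != "not_applicable"],
        columns=["stay_id", "rule_id", "status", "start", "end", "outcome"],
    ).set_index("stay_id")
    y = frame.outcome.to_numpy(dtype=float)
    exposed = (frame.status == "exposed").to_numpy(dtype=float)
    if dummies is None:
        dummies = design_matrix(profiles)
    dummies_sub = dummies.loc[frame.index]

    p_exp = table.a / table.n_exposed if table.n_exposed else float("nan")
    n_non = table.c + table.d
    p_non = table.c / n_non if n_non else float("nan")
    return RuleEstimate(
        rule_id=rule.rule_id,
        n_exposed=n_exposed,
        table=table,
        status="estimated",
        or_unadjusted=fisher_or(table, config.alpha),
        or_adjusted=adjusted_or(y, exposed, dummies_sub, config.alpha, config.separation_bound),
        or_stepwise=stepwise_or(y, exposed, dummies_sub, config.alpha, config.separation_bound),
        p_outcome_exposed=p_exp,
        p_outcome_nonexposed=p_non,
    )


def estimate_all_rules(
    subcohort,
    rules,
    profiles: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[RuleEstimate]:
    """One :class:`RuleEstimate` per rule, over the full included-stay set."""
    index = _CohortIndex(subcohort, config)
    dummies = design_matrix(profiles)
    return [
        estimate_rule(rule, subcohort, profiles, config, index=index, dummies=dummies)
        for rule in rules
    ]
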