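"""Exploratory predictor selection over extended covariates.

The selection pipeline mirrors common epidemiological practice: an
unadjusted (single-predictor) Cox screen at a liberal alpha, then either
backward elimination on Wald p-values or greedy forward stepwise search
minimising an information criterion.  In these exploratory models the lipid
and blood-pressure variables enter as continuous predictors, and skewed
laboratory values (creatinine, triglycerides) enter on the log scale.

Criteria: AIC = -2 logPL + 2k and BIC = -2 logPL + k log(d), with k the
number of coefficients and d the number of events (the survival-analysis
convention for the effective sample size; configurable to n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DomainError, FitError
from .categories import DEFAULT_SCHEME, CategoryScheme
from .cohort import CohortTable
from .coxfit import CoxFit, TermSpec, fit_cox

__all__ = [
    "SelectionScore", "SelectionStep", "SelectionTrace",
    "selection_score", "univariate_screen", "backward_select", "forward_stepwise",
    "DEFAULT_CANDIDATES",
]

#: default candidate pool: traditional risk factors plus routinely available
#: lifestyle / laboratory variables (continuous forms; skewed ones logged)
DEFAULT_CANDIDATES = (
    "age", "female", "smoking:current", "hypertension", "diabetes",
    "bmi", "waist_cm", "sbp", "dbp", "hdl_cholesterol", "tc_hdl_ratio",
    "glucose", "log_creatinine", "aspirin", "physical_activity_high",
)


@dataclass
class SelectionScore:
    terms: tuple[str, ...]
    log_likelihood: float
    k: int
    n_events: int
    aic: float
    bic: float
    wald_p: dict[str, float]


@dataclass
class SelectionStep:
    action: str             # "add" | "remove"
    term: str
    before: float           # criterion (or max p) before the step
    after: float            # criterion (or max p) after the step


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_terms: tuple[str, ...]
    criterion: str
    final_score: SelectionScore | None = None


def _wald_p(fit: CoxFit) -> dict[str, float]:
    if len(fit.params) == 0:
        return {}
    z = fit.params / fit.standard_errors
    return {t: float(2 * stats.norm.sf(abs(zv))) for t, zv in z.items()}


def selection_score(fit: CoxFit, events_as_n: bool = True) -> SelectionScore:
    """AIC/BIC bookkeeping for a fit; BIC sample size defaults to the event count."""
    k = len(fit.params)
    n_for_bic = fit.n_events if events_as_n else fit.n
    ll = fit.log_likelihood
    return SelectionScore(
        terms=fit.terms, log_likelihood=ll, k=k, n_events=fit.n_events,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(n_for_bic) if k else -2.0 * ll,
        wald_p=_wald_p(fit),
    )


def univariate_screen(cohort: CohortTable, candidates=DEFAULT_CANDIDATES,
                      alpha: float = 0.20,
                      scheme: CategoryScheme = DEFAULT_SCHEME
                      ) -> tuple[list[str], pd.DataFrame]:
    """Single-predictor Cox screen: retain candidates with Wald p < alpha.

    Returns (retained terms in input order, full screen table).  Candidates
    that cannot be fitted (missing column, zero variance, non-convergence)
    are recorded with NaN p and skipped.
    """
    rows = []
    retained = []
    for term in candidates:
        try:
            fit = fit_cox(cohort, (term,), scheme)
            p = _wald_p(fit)[term]
            rows.append([term, float(fit.params.iloc[0]),
                         float(np.exp(fit.params.iloc[0])), p, ""])
            if p < alpha:
                retained.append(term)
        except (FitError, KeyError, DomainError) as exc:
            rows.append([term, np.nan, np.nan, np.nan, f"skipped: {exc}"])
    table = pd.DataFrame(rows, columns=["term", "coef", "hr", "p", "note"]).set_index("term")
    return retained, table


def backward_select(cohort: CohortTable, terms, p_stay: float = 0.10,
                    scheme: CategoryScheme = DEFAULT_SCHEME) -> SelectionTrace:
    """Backward elimination: drop the worst term with Wald p >= p_stay, refit, repeat."""
    current = list(terms)
    steps: list[SelectionStep] = []
    if not current:
        return SelectionTrace(steps=[], final_terms=(), criterion=f"p<{p_stay}")
    fit = fit_cox(cohort, current, scheme)
    while current:
        pvals = _wald_p(fit)
        worst = max(current, key=lambda t: pvals[t])
        if pvals[worst] < p_stay:
            break
        current.remove(worst)
        new_fit = fit_cox(cohort, current, scheme) if current else fit_cox(cohort, (), scheme)
        new_p = max(_wald_p(new_fit).values(), default=0.0)
        steps.append(SelectionStep("remove", worst, pvals[worst], new_p))
        fit = new_fit
    score = selection_score(fit)
    return SelectionTrace(steps=steps, final_terms=tuple(current),
                          criterion=f"p<{p_stay}", final_score=score)


def forward_stepwise(cohort: CohortTable, candidates, criterion: str = "aic",
                     scheme: CategoryScheme = DEFAULT_SCHEME,
                     events_as_n: bool = True) -> SelectionTrace:
    """Greedy forward search minimising AIC or BIC, starting from the null model.

    At each step the candidate giving the largest criterion decrease is
    added; the search stops when no addition decreases the criterion.  BIC's
    log-n penalty uses the event count, so it prunes harder than AIC and its
    selected set is (on typical data) a subset of the AIC set.
    """
    if criterion not in ("aic", "bic"):
        raise DomainError("criterion must be 'aic' or 'bic'")
    current: list[str] = []
    remaining = list(candidates)
    fit = fit_cox(cohort, (), scheme)
    best = getattr(selection_score(fit, events_as_n), criterion)
    steps: list[SelectionStep] = []
    while remaining:
        trial_scores = {}
        for term in remaining:
            try:
                tfit = fit_cox(cohort, tuple(current) + (term,), scheme)
            except (FitError, KeyError, DomainError):
                continue
            trial_scores[term] = getattr(selection_score(tfit, events_as_n), criterion)
        if not trial_scores:
            break
        term = min(trial_scores, key=trial_scores.get)
        if trial_scores[term] >= best:
            break
        steps.append(SelectionStep("add", term, best, trial_scores[term]))
        best = trial_scores[term]
        current.append(term)
        remaining.remove(term)
    final_fit = fit_cox(cohort, tuple(current), scheme)
    return SelectionTrace(steps=steps, final_terms=tuple(current), criterion=criterion,
                          final_score=selection_score(final_fit, events_as_n))
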