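"""Exploratory predictor selection over lifestyle and laboratory covariates.

A liberal univariate screen (p < 0.20) feeds three strategies: backward
elimination (retain p < 0.10) and forward stepwise search minimising AIC or
BIC (BIC penalises model size by log(number of events), so it keeps fewer
terms).  Under the default generator only the traditional risk factors
carry signal, so extended covariates should mostly be screened out.
"""

from chdrisk import (CohortSpec, backward_select, forward_stepwise, generate,
                     univariate_screen)

cohort = generate(CohortSpec(), seed=42)

candidates = ("age", "female", "smoking:current", "hypertension", "diabetes",
              "bmi", "waist_cm", "sbp", "dbp", "hdl_cholesterol",
              "tc_hdl_ratio", "glucose", "log_creatinine", "aspirin",
              "physical_activity_high")
retained, table = univariate_screen(cohort, candidates, alpha=0.20)
print("univariate screen (p < 0.20) retained:", retained)

back = backward_select(cohort, tuple(retained), p_stay=0.10)
print("backward (p < 0.10):", list(back.final_terms))

for crit in ("aic", "bic"):
    trace = forward_stepwise(cohort, retained, criterion=crit)
    score = trace.final_score
    print(f"forward {crit.upper()}: {list(trace.final_terms)} "
          f"({crit}={getattr(score, crit):.1f}, events={score.n_events})")
# BIC's final model is expected to be a subset of AIC's; both should retain
# the strongest traditional risk factors.
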