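"""Recalibration of an external risk equation to a target cohort.

Recalibration keeps the original Cox coefficients but replaces (i) the
reference means with the target cohort's own term means and (ii) the
baseline survival with the cohort's Kaplan-Meier estimate at the analysis
horizon.  Because the linear predictor is unchanged up to an additive
constant and the survival base is a constant, recalibration is a strictly
monotone transform of the original score: per-person risk ranks — and hence
Harrell's C — are exactly preserved, while absolute risk levels shift to
match the target population's event rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._exceptions import DomainError
from .categories import DEFAULT_SCHEME, CategoryScheme, build_design
from .coefficients import BaselineSurvival, CoefficientSet
from .cohort import CohortTable

__all__ = ["KMEstimate", "cohort_means", "km_survival", "recalibrate"]


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate evaluated at one time point.

    ``survival`` holds the full step function (indexed by time); ``value``
    is the right-continuous evaluation at ``time`` (the step at the largest
    event time <= t).  Events precede censorings in tied risk-set updates.
    """

    survival: pd.Series
    time: float
    value: float

    def at(self, t: float) -> float:
        times = self.survival.index.to_numpy(dtype=float)
        idx = np.searchsorted(times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival.iloc[idx])


def km_survival(cohort_or_times, t: float, events=None) -> KMEstimate:
    """Kaplan-Meier survival at time ``t`` under right censoring.

    Accepts either a :class:`CohortTable` or explicit ``(times, events)``
    arrays.  ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over event times.
    """
    if t < 0:
        raise DomainError(f"evaluation time must be >= 0, got {t}")
    if isinstance(cohort_or_times, CohortTable):
        times = cohort_or_times.df["time"].to_numpy(dtype=float)
        events = cohort_or_times.df["event"].to_numpy(dtype=float)
    else:
        times = np.asarray(cohort_or_times, dtype=float)
        events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise DomainError("cannot estimate a survival function from an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_.iloc[:, 0]
    est = KMEstimate(survival=surv, time=t, value=np.nan)
    est.value = est.at(t)
    return est


def cohort_means(cohort: CohortTable, coefs: CoefficientSet,
                 scheme: CategoryScheme = DEFAULT_SCHEME) -> dict[str, float]:
    """Cohort means of the equation's transformed terms.

    Indicator terms yield category prevalences; ``age_sq`` yields the mean
    of squared ages (not the square of the mean age).
    """
    if len(cohort) == 0:
        raise DomainError("cannot compute term means on an empty cohort")
    X = build_design(cohort.df, coefs.terms, scheme)
    return {t: float(v) for t, v in X.mean().items()}


def recalibrate(coefs: CoefficientSet, cohort: CohortTable, t: float | None = None,
                scheme: CategoryScheme = DEFAULT_SCHEME) -> CoefficientSet:
    """Recalibrated equation: same betas, cohort means, cohort KM baseline.

    The cohort must already be stratified to the equation's sex.  The
    returned set is tagged ``recalibrated`` and its baseline survival is the
    cohort Kaplan-Meier value at ``t`` (default: cohort horizon), so a person
    at the cohort mean profile is assigned risk exactly ``1 - KM(t)``.
    """
    if t is None:
        t = cohort.horizon
    sexes = set(cohort.df["sex"].unique())
    if sexes - {coefs.sex}:
        raise DomainError(f"cohort contains sex(es) {sorted(sexes)} but the "
                          f"equation is for {coefs.sex!r}; stratify first")
    means = cohort_means(cohort, coefs, scheme)
    km = km_survival(cohort, t)
    if not (0.0 < km.value < 1.0):
        raise DomainError(f"Kaplan-Meier survival at t={t} is {km.value}; "
                          "recalibration needs a baseline strictly inside (0,1)")
    return replace(
        coefs,
        reference_means=means,
        baseline_survival=BaselineSurvival(km.value, t, method="kaplan_meier"),
        provenance="recalibrated",
    )
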