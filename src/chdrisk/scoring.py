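"""Sex-specific Framingham-type CHD risk scoring at an arbitrary horizon.

The predicted probability of a CHD event by time ``t`` for a person with
linear predictor ``L`` is

    p = 1 - S0(t) ** exp(L - Lbar),

with ``S0(t)`` the baseline survival at the mean risk profile and ``Lbar``
the linear predictor evaluated at the reference means.  ``L`` is built from
the categorised risk factors (NCEP cholesterol bins, JNC blood-pressure
stages, diabetes and current smoking) plus continuous age — and, in the
women's equation, age squared, which makes predicted risk peak near age 63
and decline slowly thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DomainError
from .categories import DEFAULT_SCHEME, CategoryScheme, build_design
from .coefficients import BaselineSurvival, CoefficientSet
from .cohort import CohortTable

__all__ = ["PredictedRisk", "linear_predictor", "predicted_risk", "frs_score", "risk_class"]

#: 10-year CHD risk classes (percent), <5 / 5-9.99 / 10-19.99 / >=20
RISK_CLASS_EDGES = (0.05, 0.10, 0.20)
RISK_CLASS_LABELS = ("<5%", "5-9.99%", "10-19.99%", ">=20%")


@dataclass
class PredictedRisk:
    """Per-person predicted event probabilities by a horizon."""

    values: np.ndarray
    horizon: float
    model: str = "frs"
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1):
            raise DomainError("predicted risks must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        idx = self.ids if self.ids is not None else np.arange(self.values.size)
        return pd.Series(self.values, index=idx, name=f"risk_{self.model}")


def linear_predictor(records: pd.DataFrame, coefs: CoefficientSet,
                     scheme: CategoryScheme = DEFAULT_SCHEME) -> np.ndarray:
    """L = sum_j beta_j x_j for every record, using the set's term vocabulary."""
    X = build_design(records, coefs.terms, scheme)
    beta = np.array([coefs.coefficients[t] for t in coefs.terms])
    return X.to_numpy() @ beta


def predicted_risk(L, L_bar: float, s0: BaselineSurvival) -> np.ndarray:
    """Absolute risk 1 - S0 ** exp(L - Lbar); strictly increasing in L."""
    L = np.asarray(L, dtype=float)
    return 1.0 - s0.value ** np.exp(L - L_bar)


def frs_score(cohort: CohortTable, coef_sets: dict[str, CoefficientSet] | CoefficientSet,
              t: float | None = None, scheme: CategoryScheme = DEFAULT_SCHEME,
              model: str | None = None) -> PredictedRisk:
    """Score every cohort member with the sex-matched risk equation.

    ``coef_sets`` maps sex to :class:`CoefficientSet` (a single set is
    accepted for a single-sex cohort).  Baseline survivals are rescaled to
    horizon ``t`` (default: the cohort's horizon) with the exponential model
    when they are stored at a different horizon.
    """
    if t is None:
        t = cohort.horizon
    if isinstance(coef_sets, CoefficientSet):
        coef_sets = {coef_sets.sex: coef_sets}
    sexes = set(cohort.df["sex"].unique())
    missing = sexes - set(coef_sets)
    if missing:
        raise DomainError(f"no coefficient set for sex(es): {sorted(missing)}")
    risks = np.full(len(cohort), np.nan)
    tag = model
    for sex, sub in cohort.df.groupby("sex"):
        cs = coef_sets[sex].at_horizon(t)
        L = linear_predictor(sub, cs, scheme)
        risks[sub.index.to_numpy()] = predicted_risk(L, cs.mean_linear_predictor(),
                                                     cs.baseline_survival)
        if tag is None:
            tag = cs.provenance or "frs"
    return PredictedRisk(values=risks, horizon=t, model=tag or "frs",
                         ids=cohort.df["id"].to_numpy())


def risk_class(risk10) -> np.ndarray:
    """Classify 10-year risks into the standard <5 / 5-9.99 / 10-19.99 / >=20 % bands."""
    r = np.asarray(risk10, dtype=float)
    idx = np.searchsorted(np.asarray(RISK_CLASS_EDGES), r, side="right")
    return np.asarray(RISK_CLASS_LABELS, dtype=object)[idx]
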