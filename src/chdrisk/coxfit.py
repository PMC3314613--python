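"""Cox proportional-hazards refit of the risk equation on a target cohort.

Refitting re-estimates the category coefficients on the cohort itself
("the cohort's own function"), with adjacent risk-factor categories pooled
where the data hold too few events to support a separate coefficient.  The
fit maximises the Efron partial likelihood (delegated to lifelines); its
baseline survival at the covariate means — the Breslow estimator evaluated
at the mean profile — replaces the external baseline, and the
Therneau-Grambsch Schoenfeld-residual test checks proportionality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import TimeTransformers, proportional_hazard_test
from scipy import stats

from ._exceptions import ConvergenceError, DomainError, FitError, ZeroVarianceError
from .categories import DEFAULT_SCHEME, CategoryScheme, build_design
from .coefficients import BaselineSurvival
from .cohort import CohortTable
from .scoring import PredictedRisk, predicted_risk

__all__ = [
    "TermSpec", "CoxFit", "PHTestResult",
    "fit_cox", "hazard_ratios", "baseline_survival_at_means", "refit_risk", "ph_test",
]


@dataclass(frozen=True)
class TermSpec:
    """Ordered model terms for a refit, with category pooling spelled out.

    Terms use the shared vocabulary of :mod:`chdrisk.categories`; pooled
    categories are written ``factor:lvl1|lvl2``.  The default specs pool the
    categories whose separate cells hold too few events in an elderly cohort
    (and drop total cholesterol and age squared for women, where they are
    unpredictive); the exact pooling of sparse extreme cells is a judgement
    call and both defaults are plain data, fully overridable.
    """

    terms: tuple[str, ...]
    sex: str | None = None
    notes: str = ""

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise DomainError("duplicate terms in TermSpec")

    @classmethod
    def default_female(cls) -> "TermSpec":
        return cls(
            terms=("age", "hdl:<35|35-44", "hdl:45-49", "hdl:>=60",
                   "bp:optimal", "bp:high_normal", "bp:stage1|stage2_4",
                   "diabetes", "smoking:current"),
            sex="female",
            notes="TC and age^2 omitted (unpredictive in elderly women); "
                  "HDL <35 pooled with 35-44; BP stages I-IV pooled. "
                  "Reference levels: HDL 50-59, BP normal, never/former smoking.",
        )

    @classmethod
    def default_male(cls) -> "TermSpec":
        return cls(
            terms=("age", "tc:<160", "tc:240-279|>=280",
                   "hdl:50-59", "hdl:>=60",
                   "bp:optimal", "bp:high_normal|stage1|stage2_4",
                   "diabetes", "smoking:current"),
            sex="male",
            notes="TC 200-239 pooled with the 160-199 referent; TC >=280 pooled "
                  "with 240-279; HDL referent pooled as <50; BP high-normal and "
                  "stages I-IV pooled (pooling of sparse cells inferred, overridable).",
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"terms": list(self.terms), "sex": self.sex, "notes": self.notes},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TermSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(terms=tuple(d["terms"]), sex=d.get("sex"), notes=d.get("notes", ""))


@dataclass
class CoxFit:
    """A converged Cox partial-likelihood fit on a cohort."""

    params: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    terms: tuple[str, ...]
    converged: bool = True
    #: design matrix + time/event actually fitted (kept for baselines, residuals)
    design: pd.DataFrame | None = None
    _fitter: CoxPHFitter | None = None


@dataclass
class PHTestResult:
    """Therneau-Grambsch proportional-hazards test (Schoenfeld residuals)."""

    per_term: pd.DataFrame  # columns: chi2, p (df=1 each)
    global_chi2: float
    global_df: int
    global_p: float
    time_transform: str = "km"


def _null_log_partial_likelihood(times: np.ndarray, events: np.ndarray) -> float:
    """Efron log partial likelihood of the model with no covariates.

    At a time with d tied events and risk set of size n the contribution is
    -sum_{l=0}^{d-1} log(n - l); for distinct event times this reduces to
    -log(risk-set size) per event.
    """
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    ll = 0.0
    n = times.size
    for t in np.unique(times[events > 0]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events > 0)))
        ll -= sum(np.log(at_risk - l) for l in range(d))
    return ll


def fit_cox(cohort: CohortTable, terms: TermSpec | tuple[str, ...] | list[str],
            scheme: CategoryScheme = DEFAULT_SCHEME) -> CoxFit:
    """Maximise the Efron partial likelihood for the given terms.

    Raises :class:`ZeroVarianceError` naming any constant term,
    :class:`ConvergenceError` on failed Newton iterations, and
    :class:`FitError` for a cohort without events.  ``terms`` may be empty,
    giving the null model (useful as the base of stepwise selection).
    """
    if not isinstance(terms, TermSpec):
        terms = TermSpec(terms=tuple(terms))
    df = cohort.df
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=float)
    d = int(events.sum())
    if d < 1:
        raise FitError("cohort contains no events; cannot fit a Cox model")
    X = build_design(df, list(terms.terms), scheme)
    for t in terms.terms:
        if np.ptp(X[t].to_numpy()) == 0.0:
            raise ZeroVarianceError(t)
    fit_df = X.copy()
    fit_df["time"] = times
    fit_df["event"] = events
    if not terms.terms:
        ll = _null_log_partial_likelihood(times, events)
        empty = pd.Series(dtype=float)
        return CoxFit(params=empty, standard_errors=empty,
                      covariance=pd.DataFrame(dtype=float), log_likelihood=ll,
                      n=len(df), n_events=d, terms=(), design=fit_df)
    fitter = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(fit_df, duration_col="time", event_col="event",
                       fit_options={"precision": 1e-10, "r_precision": 0.0,
                                    "max_steps": 500})
    except _LLConvergenceError as exc:
        msg = str(exc)
        if "complete separation" in msg or "monotone" in msg.lower():
            raise ConvergenceError(f"monotone partial likelihood (separation?): {msg}")
        raise ConvergenceError(msg)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix (collinear terms?): {exc}")
    params = fitter.params_.copy()
    if not np.all(np.isfinite(params.to_numpy())):
        raise ConvergenceError("non-finite coefficients returned")
    return CoxFit(
        params=params,
        standard_errors=fitter.standard_errors_.copy(),
        covariance=fitter.variance_matrix_.copy(),
        log_likelihood=float(fitter.log_likelihood_),
        n=len(df), n_events=d, terms=terms.terms,
        design=fit_df, _fitter=fitter,
    )


def hazard_ratios(fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term hazard ratios with Wald confidence intervals.

    HR = exp(beta), CI = exp(beta +/- z_{1-alpha/2} * SE).
    """
    z = stats.norm.ppf(1 - alpha / 2)
    beta = fit.params
    se = fit.standard_errors
    return pd.DataFrame({
        "coef": beta,
        "se": se,
        "hr": np.exp(beta),
        "hr_lower": np.exp(beta - z * se),
        "hr_upper": np.exp(beta + z * se),
    })


def baseline_survival_at_means(fit: CoxFit, t: float) -> BaselineSurvival:
    """Breslow baseline survival of the fit, at the covariate means, at time ``t``.

    For the null model this is the Nelson-Aalen based survival
    ``exp(-sum d_i/n_i)``.  Beyond the last observed time the last value is
    carried forward with a warning.
    """
    if t <= 0:
        raise DomainError(f"evaluation time must be positive, got {t}")
    times = fit.design["time"].to_numpy(dtype=float)
    if t > times.max():
        warnings.warn(f"t={t} exceeds the last observed time {times.max():.3g}; "
                      "carrying the last baseline value forward", stacklevel=2)
        t = float(times.max())
    if fit._fitter is None:
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, event_observed=fit.design["event"].to_numpy())
        ch = naf.cumulative_hazard_.iloc[:, 0]
        idx = np.searchsorted(ch.index.to_numpy(dtype=float), t, side="right") - 1
        value = float(np.exp(-ch.iloc[idx])) if idx >= 0 else 1.0
    else:
        surv = fit._fitter.baseline_survival_.iloc[:, 0]
        grid = surv.index.to_numpy(dtype=float)
        idx = np.searchsorted(grid, t, side="right") - 1
        value = float(surv.iloc[idx]) if idx >= 0 else 1.0
    # clamp into the open interval required of a survival probability
    value = min(max(value, 1e-12), 1.0 - 1e-12)
    return BaselineSurvival(value=value, horizon=t, method="cox_at_means")


def refit_risk(fit: CoxFit, cohort: CohortTable, t: float | None = None,
               scheme: CategoryScheme = DEFAULT_SCHEME) -> PredictedRisk:
    """Per-person risk from the refit equation: 1 - S0(t|xbar) ** exp(L - Lbar)."""
    if t is None:
        t = cohort.horizon
    X = build_design(cohort.df, list(fit.terms), scheme)
    beta = fit.params.reindex(list(fit.terms)).to_numpy() if len(fit.terms) else np.zeros(0)
    L = X.to_numpy() @ beta if len(fit.terms) else np.zeros(len(cohort))
    Xbar = fit.design[list(fit.terms)].mean().to_numpy() if len(fit.terms) else np.zeros(0)
    L_bar = float(Xbar @ beta) if len(fit.terms) else 0.0
    s0 = baseline_survival_at_means(fit, t)
    return PredictedRisk(values=predicted_risk(L, L_bar, s0), horizon=t,
                         model="refit", ids=cohort.df["id"].to_numpy())


def ph_test(fit: CoxFit, time_transform: str = "km") -> PHTestResult:
    """Therneau-Grambsch proportional-hazards test.

    Regresses scaled Schoenfeld residuals on a transform of event time
    (default: the Kaplan-Meier transform ``1 - KM(t)``); per-term chi-squares
    on 1 df plus the global score test on ``p`` df.  With a single term the
    global statistic equals the per-term statistic.
    """
    if fit._fitter is None:
        raise FitError("PH test requires a fitted model with at least one term")
    if fit.n_events < 2:
        raise FitError("PH test requires at least 2 events")
    fitter = fit._fitter
    res = proportional_hazard_test(fitter, fit.design, time_transform=time_transform)
    per_term = pd.DataFrame({
        "chi2": res.summary["test_statistic"].to_numpy(),
        "p": res.summary["p"].to_numpy(),
    }, index=fit.params.index)

    # global statistic: u' V^{-1} u / (d * sum((g - gbar)^2)) with
    # u = sum_k (g_k - gbar) * r*_k over scaled Schoenfeld residuals r*.
    scaled = fitter.compute_residuals(fit.design, kind="scaled_schoenfeld")
    durations, events_s, weights = fitter.durations, fitter.event_observed, fitter.weights
    transform = TimeTransformers().get(time_transform)
    g = np.asarray(transform(durations, events_s, weights))[events_s.values.astype(bool)]
    g = g - g.mean()
    d = int(events_s.sum())
    u = (g[:, None] * scaled.to_numpy()).sum(axis=0)
    V = fit.covariance.to_numpy()
    chi2 = float(u @ np.linalg.solve(V, u) / (d * (g ** 2).sum()))
    p = float(stats.chi2.sf(chi2, df=len(fit.params)))
    return PHTestResult(per_term=per_term, global_chi2=chi2, global_df=len(fit.params),
                        global_p=p, time_transform=time_transform)
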