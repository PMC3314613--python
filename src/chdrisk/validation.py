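"""Discrimination and calibration of per-person risk scores under censoring.

Discrimination is Harrell's C: among usable subject pairs (the member with
the shorter observed time had an event), the fraction in which the
earlier-event subject carries the higher score, ties in score counting 1/2.
Because C depends on scores only through their ranks, any strictly
increasing rescaling of a score — recalibration in particular — leaves it
unchanged.  In-sample C of a refit model is corrected for optimism by
Harrell's bootstrap: refit on each resample, measure the drop from
resample-C to original-data-C, and subtract the average drop.

Calibration uses a censoring-aware Hosmer-Lemeshow-type chi-square over
deciles of predicted risk: expected failures E_g are the summed predicted
risks, observed failures O_g are n_g * (1 - KM_g(t)) with the within-decile
Kaplan-Meier, and

    X^2 = sum_g (O_g - E_g)^2 / (E_g * (1 - E_g / n_g)),   df = groups - 1.

The degrees of freedom follow the groups-minus-one convention; larger p
indicates better calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DomainError, FitError
from .categories import DEFAULT_SCHEME, CategoryScheme, build_design
from .cohort import CohortTable
from .recalibrate import km_survival

__all__ = [
    "ConcordanceResult", "CalibrationResult",
    "harrell_c", "optimism_corrected_c", "hl_cox", "decile_ratio", "compare_c",
]


@dataclass
class ConcordanceResult:
    c: float
    n_usable_pairs: int
    apparent: float | None = None
    optimism: float | None = None
    n_bootstrap: int | None = None
    seed: int | None = None


@dataclass
class CalibrationResult:
    table: pd.DataFrame  # per group: n, observed, expected
    statistic: float
    df: int
    p: float
    merged_groups: int = 0


def _as_arrays(times, events, *scores):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    out = [np.asarray(s, dtype=float) for s in scores]
    if any(a.shape != times.shape for a in (events, *out)):
        raise DomainError("times, events and scores must have equal length")
    return (times, events, *out)


def harrell_c(times, events, scores) -> ConcordanceResult:
    """Harrell's concordance index for right-censored outcomes.

    Usable pairs (i, j): the smaller observed time belongs to an event.
    Concordant when that subject has the strictly higher score; score ties
    count 0.5.  Pairs with tied observed times are not usable.
    """
    times, events, scores = _as_arrays(times, events, scores)
    n = times.size
    conc = 0.0
    usable = 0
    # O(n^2) in vectorised blocks; n is cohort-sized (thousands) at most
    block = 512
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        ti = times[sl, None]
        ei = events[sl, None]
        si = scores[sl, None]
        earlier_i = (ti < times[None, :]) & (ei > 0)   # i earlier, i event
        usable += int(earlier_i.sum())
        conc += float(np.sum(earlier_i & (si > scores[None, :])))
        conc += 0.5 * float(np.sum(earlier_i & (si == scores[None, :])))
    if usable == 0:
        raise FitError("no usable pairs: cannot compute a concordance index")
    # each unordered usable pair counted once (as the i-earlier ordered pair)
    return ConcordanceResult(c=conc / usable, n_usable_pairs=usable)


def optimism_corrected_c(cohort: CohortTable, terms, B: int = 200, seed: int = 0,
                         scheme: CategoryScheme = DEFAULT_SCHEME) -> ConcordanceResult:
    """Bootstrap optimism-corrected C of a refit Cox model (Harrell's procedure).

    Apparent C is the in-sample concordance of the model fitted to the full
    cohort.  Each bootstrap resample refits the model; its optimism is
    C(resample model on resample) - C(resample model on original data).
    Corrected C = apparent - mean optimism.  A resample whose fit fails is
    logged and redrawn (at most 2B attempts).
    """
    from .coxfit import TermSpec, fit_cox  # local import to avoid a cycle

    if B < 1:
        raise DomainError("B must be >= 1")
    if not isinstance(terms, TermSpec):
        terms = TermSpec(terms=tuple(terms))
    rng = np.random.default_rng(seed)
    df = cohort.df
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=float)
    X_full = build_design(df, list(terms.terms), scheme).to_numpy()

    fit = fit_cox(cohort, terms, scheme)
    beta = fit.params.to_numpy()
    apparent = harrell_c(times, events, X_full @ beta).c

    optimisms = []
    attempts = 0
    n = len(df)
    while len(optimisms) < B and attempts < 2 * B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        boot = CohortTable(df.iloc[idx].assign(id=np.arange(n).astype(str)),
                           horizon=cohort.horizon)
        try:
            bfit = fit_cox(boot, terms, scheme)
        except FitError:
            continue
        bbeta = bfit.params.to_numpy()
        c_boot = harrell_c(times[idx], events[idx], X_full[idx] @ bbeta).c
        c_orig = harrell_c(times, events, X_full @ bbeta).c
        optimisms.append(c_boot - c_orig)
    if len(optimisms) < B:
        raise FitError(f"only {len(optimisms)}/{B} bootstrap fits succeeded")
    optimism = float(np.mean(optimisms))
    return ConcordanceResult(c=apparent - optimism, n_usable_pairs=0,
                             apparent=apparent, optimism=optimism,
                             n_bootstrap=B, seed=seed)


def _risk_groups(risks: np.ndarray, groups: int) -> list[np.ndarray]:
    """Index blocks for near-equal groups of increasing predicted risk.

    Stable sort on (risk, position) so boundary ties split deterministically.
    """
    order = np.lexsort((np.arange(risks.size), risks))
    return [g for g in np.array_split(order, groups) if g.size > 0]


def hl_cox(risks, times, events, t: float, groups: int = 10) -> CalibrationResult:
    """Censoring-aware Hosmer-Lemeshow chi-square over risk deciles.

    Groups with no expected events are merged into their lower neighbour
    (reducing the degrees of freedom); ``merged_groups`` reports how many.
    """
    times, events, risks = _as_arrays(times, events, risks)
    if groups < 1:
        raise DomainError("groups must be >= 1")
    if groups > times.size:
        raise DomainError("more groups than subjects")
    blocks = _risk_groups(risks, groups)
    rows = []
    for g in blocks:
        n_g = g.size
        e_g = float(risks[g].sum())
        km = km_survival(times[g], t, events[g])
        o_g = n_g * (1.0 - km.value)
        rows.append([n_g, o_g, e_g, float(risks[g].mean())])
    tab = pd.DataFrame(rows, columns=["n", "observed", "expected", "mean_predicted"])
    # merge zero-expectation groups downward so every cell has E > 0
    merged = 0
    i = 0
    while i < len(tab):
        if tab.loc[i, "expected"] <= 0 and len(tab) > 1:
            j = i - 1 if i > 0 else i + 1
            tab.loc[j, ["n", "observed", "expected"]] += tab.loc[i, ["n", "observed", "expected"]]
            tab = tab.drop(index=i).reset_index(drop=True)
            merged += 1
        else:
            i += 1
    n_g = tab["n"].to_numpy(dtype=float)
    o = tab["observed"].to_numpy()
    e = tab["expected"].to_numpy()
    denom = e * np.clip(1.0 - e / n_g, 1e-12, None)
    statistic = float(np.sum((o - e) ** 2 / denom))
    df_ = max(len(tab) - 1, 1)
    p = float(stats.chi2.sf(statistic, df=df_))
    return CalibrationResult(table=tab, statistic=statistic, df=df_, p=p,
                             merged_groups=merged)


def decile_ratio(risks, times, events, t: float, groups: int = 10) -> pd.DataFrame:
    """Predicted/observed risk ratio per decile of predicted risk, plus overall.

    Observed risk within a group is 1 - KM_g(t).  A group with zero observed
    risk gets ratio NaN.  The last row, labelled ``overall``, compares the
    cohort-wide mean predicted risk with the cohort-wide observed risk.
    """
    times, events, risks = _as_arrays(times, events, risks)
    blocks = _risk_groups(risks, groups)
    rows = []
    for i, g in enumerate(blocks, start=1):
        pred = float(risks[g].mean())
        obs = 1.0 - km_survival(times[g], t, events[g]).value
        rows.append([str(i), g.size, pred, obs, pred / obs if obs > 0 else np.nan])
    pred_all = float(risks.mean())
    obs_all = 1.0 - km_survival(times, t, events).value
    rows.append(["overall", times.size, pred_all, obs_all,
                 pred_all / obs_all if obs_all > 0 else np.nan])
    return pd.DataFrame(rows, columns=["group", "n", "mean_predicted",
                                       "observed", "ratio"]).set_index("group")


def compare_c(times, events, scores_a, scores_b, B: int = 500, seed: int = 0) -> dict:
    """Bootstrap two-sided test of C(scores_a) - C(scores_b) on the same subjects.

    Subjects are resampled with replacement; the p-value is two-sided from
    the quantile position of 0 in the bootstrap distribution of the
    difference.  Rank-equivalent scores give difference exactly 0 in every
    replicate and p = 1.
    """
    times, events, scores_a, scores_b = _as_arrays(times, events, scores_a, scores_b)
    rng = np.random.default_rng(seed)
    c_a = harrell_c(times, events, scores_a).c
    c_b = harrell_c(times, events, scores_b).c
    diffs = np.empty(B)
    n = times.size
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            diffs[b] = (harrell_c(times[idx], events[idx], scores_a[idx]).c
                        - harrell_c(times[idx], events[idx], scores_b[idx]).c)
        except FitError:
            diffs[b] = np.nan
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        raise FitError("all bootstrap replicates were degenerate")
    if np.all(diffs == 0.0):
        p = 1.0
    else:
        lower = float(np.mean(diffs <= 0.0))
        upper = float(np.mean(diffs >= 0.0))
        p = min(1.0, 2.0 * min(lower, upper))
    return {"c_a": c_a, "c_b": c_b, "difference": c_a - c_b, "p": p,
            "n_bootstrap": int(diffs.size), "seed": seed}
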