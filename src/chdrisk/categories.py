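"""Risk-factor categorisation and model-term construction.

The sex-specific Framingham CHD equations of Wilson et al. enter total
cholesterol, HDL cholesterol and blood pressure as NCEP / JNC category
indicators rather than continuous values.  This module defines the category
scheme (bin edges), categorises cohort tables under it, and builds numeric
design columns for a shared term vocabulary used by the scoring,
recalibration, refitting and simulation code.

Term vocabulary
---------------
Continuous / numeric terms (resolved against cohort columns):
    ``age``, ``age_sq`` (age squared), ``diabetes``, ``sbp``, ``dbp``,
    ``total_cholesterol``, ``hdl_cholesterol``, ``tc_hdl_ratio``,
    ``log_creatinine``, ``log_triglycerides``, or any numeric column name
    present in the table (``bmi``, ``glucose``, ``aspirin``, ...).

Categorical indicator terms, written ``factor:level`` with ``|`` pooling
adjacent levels, e.g. ``tc:<160``, ``hdl:<35|35-44``, ``bp:stage1|stage2_4``,
``smoking:current``.  The reference level of each factor carries no term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DomainError

TC_LEVELS = ("<160", "160-199", "200-239", "240-279", ">=280")
HDL_LEVELS = ("<35", "35-44", "45-49", "50-59", ">=60")
BP_LEVELS = ("optimal", "normal", "high_normal", "stage1", "stage2_4")
SMOKING_LEVELS = ("never", "former", "current")

FACTOR_LEVELS = {
    "tc": TC_LEVELS,
    "hdl": HDL_LEVELS,
    "bp": BP_LEVELS,
    "smoking": SMOKING_LEVELS,
}


@dataclass(frozen=True)
class CategoryScheme:
    """Bin edges for the categorical risk factors.

    Bins are left-closed, right-open ([160, 200) is labelled "160-199",
    matching the NCEP labels).  Blood-pressure category is the more severe
    of the SBP-implied and DBP-implied categories (JNC convention); the
    stage thresholds are 120/130/140/160 mmHg systolic and 80/85/90/100
    diastolic.
    """

    tc_edges: tuple[float, ...] = (160.0, 200.0, 240.0, 280.0)
    hdl_edges: tuple[float, ...] = (35.0, 45.0, 50.0, 60.0)
    sbp_edges: tuple[float, ...] = (120.0, 130.0, 140.0, 160.0)
    dbp_edges: tuple[float, ...] = (80.0, 85.0, 90.0, 100.0)

    def __post_init__(self):
        for name in ("tc_edges", "hdl_edges", "sbp_edges", "dbp_edges"):
            edges = getattr(self, name)
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise DomainError(f"{name} must be strictly increasing, got {edges}")


DEFAULT_SCHEME = CategoryScheme()


def _bin_labels(values: np.ndarray, edges: tuple[float, ...], labels: tuple[str, ...],
                what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise DomainError(f"{what} values must be finite and strictly positive")
    idx = np.searchsorted(np.asarray(edges), values, side="right")
    return np.asarray(labels, dtype=object)[idx]


def bp_category(sbp, dbp, scheme: CategoryScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Blood-pressure category: the more severe of the SBP- and DBP-implied stages."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    for name, v in (("sbp", sbp), ("dbp", dbp)):
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise DomainError(f"{name} values must be finite and strictly positive")
    sev_s = np.searchsorted(np.asarray(scheme.sbp_edges), sbp, side="right")
    sev_d = np.searchsorted(np.asarray(scheme.dbp_edges), dbp, side="right")
    return np.asarray(BP_LEVELS, dtype=object)[np.maximum(sev_s, sev_d)]


def categorize(records: pd.DataFrame, scheme: CategoryScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Categorise risk factors for a table of participant records.

    Parameters
    ----------
    records
        Table with columns ``total_cholesterol``, ``hdl_cholesterol``,
        ``sbp``, ``dbp``, ``diabetes``, ``smoking``.
    scheme
        Bin edges; defaults to the NCEP/JNC scheme.

    Returns
    -------
    DataFrame indexed like ``records`` with columns ``tc_cat``, ``hdl_cat``,
    ``bp_cat`` (string labels), ``diabetes`` and ``smoking_current``
    (0/1 indicators).
    """
    out = pd.DataFrame(index=records.index)
    out["tc_cat"] = _bin_labels(records["total_cholesterol"].to_numpy(), scheme.tc_edges,
                                TC_LEVELS, "total_cholesterol")
    out["hdl_cat"] = _bin_labels(records["hdl_cholesterol"].to_numpy(), scheme.hdl_edges,
                                 HDL_LEVELS, "hdl_cholesterol")
    out["bp_cat"] = bp_category(records["sbp"].to_numpy(), records["dbp"].to_numpy(), scheme)
    out["diabetes"] = records["diabetes"].astype(float).to_numpy()
    smoking = records["smoking"].astype(str)
    unknown = set(smoking.unique()) - set(SMOKING_LEVELS)
    if unknown:
        raise DomainError(f"unknown smoking levels: {sorted(unknown)}")
    out["smoking_current"] = (smoking == "current").astype(float).to_numpy()
    return out


_FACTOR_COLUMN = {"tc": "tc_cat", "hdl": "hdl_cat", "bp": "bp_cat", "smoking": "smoking"}


def parse_indicator(term: str) -> tuple[str, tuple[str, ...]]:
    """Split an indicator term ``factor:lvl1|lvl2`` into (factor, levels)."""
    factor, _, rest = term.partition(":")
    levels = tuple(rest.split("|"))
    if factor not in FACTOR_LEVELS:
        raise KeyError(f"unknown factor {factor!r} in term {term!r}")
    bad = [lv for lv in levels if lv not in FACTOR_LEVELS[factor]]
    if bad:
        raise KeyError(f"unknown level(s) {bad} for factor {factor!r} in term {term!r}")
    return factor, levels


def term_column(records: pd.DataFrame, term: str,
                scheme: CategoryScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Resolve one model term to a numeric column over ``records``."""
    if ":" in term:
        factor, levels = parse_indicator(term)
        if factor == "smoking":
            cat = records["smoking"].astype(str).to_numpy()
        else:
            col = {"tc": "total_cholesterol", "hdl": "hdl_cholesterol"}.get(factor)
            if factor == "bp":
                cat = bp_category(records["sbp"], records["dbp"], scheme)
            else:
                edges = getattr(scheme, f"{factor}_edges")
                cat = _bin_labels(records[col].to_numpy(), edges,
                                  FACTOR_LEVELS[factor], col)
        return np.isin(cat, levels).astype(float)
    if term == "age":
        return records["age"].astype(float).to_numpy()
    if term == "age_sq":
        return records["age"].astype(float).to_numpy() ** 2
    if term == "female":
        return (records["sex"].astype(str) == "female").astype(float).to_numpy()
    if term == "hypertension":
        # measured-pressure definition: SBP >= 140 and/or DBP >= 90 mmHg
        return ((records["sbp"].to_numpy(dtype=float) >= 140.0)
                | (records["dbp"].to_numpy(dtype=float) >= 90.0)).astype(float)
    if term == "physical_activity_high":
        return (records["physical_activity_cat"].astype(str) == ">=1500").astype(float).to_numpy()
    if term == "alcohol_gt7":
        return (records["alcohol_cat"].astype(str) == ">7").astype(float).to_numpy()
    if term == "tc_hdl_ratio":
        return (records["total_cholesterol"] / records["hdl_cholesterol"]).to_numpy(dtype=float)
    if term == "log_creatinine":
        return np.log(records["creatinine"].to_numpy(dtype=float))
    if term == "log_triglycerides":
        return np.log(records["triglycerides"].to_numpy(dtype=float))
    if term in records.columns:
        return records[term].to_numpy(dtype=float)
    raise KeyError(f"cannot resolve model term {term!r}")


def build_design(records: pd.DataFrame, terms: list[str] | tuple[str, ...],
                 scheme: CategoryScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Numeric design matrix (one column per term) for a table of records."""
    data = {t: term_column(records, t, scheme) for t in terms}
    return pd.DataFrame(data, index=records.index)
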