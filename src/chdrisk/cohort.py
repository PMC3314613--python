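"""Cohort data model, CSV interchange and inclusion rules.

A cohort is a person-level table of demographics, traditional cardiovascular
risk factors and a right-censored time-to-CHD-event outcome.  Non-CHD deaths
are treated as censoring at the time of death, so ``event`` is binary.  The
analysis horizon (default 7.5 years, chosen to stay inside the follow-up of
an elderly cohort with ~8 years of observation) travels with the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DomainError, SchemaError

#: canonical column -> (dtype kind, required for the risk equations)
REQUIRED_COLUMNS = (
    "id", "age", "sex", "total_cholesterol", "hdl_cholesterol",
    "sbp", "dbp", "diabetes", "smoking", "time", "event",
)
#: fields whose missingness triggers exclusion (outcome fields must always be present)
RISK_FACTOR_FIELDS = (
    "age", "sex", "total_cholesterol", "hdl_cholesterol",
    "sbp", "dbp", "diabetes", "smoking",
)
OPTIONAL_COLUMNS = (
    "race", "bmi", "waist_cm", "glucose", "creatinine", "triglycerides",
    "alcohol_cat", "physical_activity_cat", "aspirin", "prevalent_cvd",
)
_NUMERIC = ("age", "total_cholesterol", "hdl_cholesterol", "sbp", "dbp",
            "time", "bmi", "waist_cm", "glucose", "creatinine", "triglycerides")
_POSITIVE = ("total_cholesterol", "hdl_cholesterol", "sbp", "dbp", "time")


@dataclass
class CohortTable:
    """An ordered person-level cohort with an analysis horizon.

    ``df`` uses the canonical column names above; ``horizon`` is the time
    point (years) at which absolute risks are evaluated.
    """

    df: pd.DataFrame
    horizon: float = 7.5

    def __post_init__(self):
        if self.horizon <= 0:
            raise DomainError(f"horizon must be positive, got {self.horizon}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table lacks required column(s): {missing}")
        ids = self.df["id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())[:5]
            raise SchemaError(f"duplicate participant ids: {dupes}")
        if len(self.df):
            t = self.df["time"].to_numpy(dtype=float)
            if np.any(~(t > 0)):
                bad = self.df.loc[~(self.df["time"] > 0), "id"].tolist()[:5]
                raise DomainError(f"follow-up time must be > 0 (ids {bad})")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def by_sex(self) -> dict[str, "CohortTable"]:
        """Sex-stratified sub-cohorts (stratified analyses are the norm here)."""
        return {s: CohortTable(g.reset_index(drop=True), self.horizon)
                for s, g in self.df.groupby("sex", sort=True)}

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True), self.horizon)


def read_cohort(path, schema: dict[str, str] | None = None, horizon: float = 7.5) -> CohortTable:
    """Read a cohort CSV, optionally renaming columns via ``schema``.

    ``schema`` maps user column names to canonical field names (e.g.
    ``{"CHOL": "total_cholesterol"}``); it may also be a path to a JSON file
    holding that mapping.  Row order is preserved.  A missing required column
    raises :class:`SchemaError` naming the column; an unparseable numeric
    value raises :class:`SchemaError` naming the participant id.
    """
    if isinstance(schema, (str,)) or hasattr(schema, "read_text"):
        with open(schema) as fh:
            schema = json.load(fh)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if schema:
        raw = raw.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = pd.DataFrame(index=raw.index)
    df["id"] = raw["id"].astype(str)
    for col in raw.columns:
        if col == "id":
            continue
        if col in _NUMERIC or col in ("diabetes", "event", "aspirin", "prevalent_cvd"):
            parsed = pd.to_numeric(raw[col], errors="coerce")
            bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
            if bad.any():
                rid = df.loc[bad, "id"].iloc[0]
                raise SchemaError(f"unparseable numeric value in column {col!r} "
                                  f"for participant id {rid!r}")
            df[col] = parsed.astype(float) if col in _NUMERIC else parsed
        else:
            df[col] = raw[col]
    for col in _POSITIVE:
        vals = df[col]
        if ((vals <= 0) & vals.notna()).any():
            rid = df.loc[(vals <= 0) & vals.notna(), "id"].iloc[0]
            raise DomainError(f"column {col!r} must be strictly positive "
                              f"(participant id {rid!r})")
    return CohortTable(df, horizon=horizon)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV (inverse of :func:`read_cohort`)."""
    cohort.df.to_csv(path, index=False)


def apply_exclusions(cohort: CohortTable) -> tuple[CohortTable, dict[str, int]]:
    """Apply the inclusion rules and return (filtered cohort, exclusion log).

    Records with prevalent cardiovascular disease (optional 0/1 column
    ``prevalent_cvd``) are dropped first; records missing any traditional
    risk factor are dropped next.  Each dropped record is counted under a
    single reason — ``prevalent_cvd`` or ``missing_<field>`` for the first
    missing field in canonical order — so that retained + logged = input.
    Idempotent: re-applying to the result changes nothing.
    """
    df = cohort.df
    log: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    if "prevalent_cvd" in df.columns:
        cvd = df["prevalent_cvd"].fillna(0).astype(float) > 0
        if cvd.any():
            log["prevalent_cvd"] = int(cvd.sum())
            keep &= ~cvd
    assigned = pd.Series(False, index=df.index)
    for fieldname in RISK_FACTOR_FIELDS:
        miss = df[fieldname].isna() & keep & ~assigned
        if fieldname in ("sex", "smoking"):
            miss |= (df[fieldname].astype(str).str.strip() == "") & keep & ~assigned
        if miss.any():
            log[f"missing_{fieldname}"] = int(miss.sum())
            assigned |= miss
    keep &= ~assigned
    return cohort.subset(keep), log
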