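"""Shared fixtures: explicit coefficient sets and small cohort builders.

Coefficient sets are constructed explicitly here (coefficients, reference
means, baseline survivals all spelled out) so no test depends on the
packaged default reference means.
"""

import numpy as np
import pandas as pd
import pytest

from chdrisk import BaselineSurvival, CoefficientSet, CohortTable

WOMEN_COEFS = {
    "age": 0.33766, "age_sq": -0.00268,
    "tc:<160": -0.26138, "tc:200-239": 0.20771, "tc:240-279": 0.24385, "tc:>=280": 0.53513,
    "hdl:<35": 0.84312, "hdl:35-44": 0.37796, "hdl:45-49": 0.19785, "hdl:>=60": -0.42951,
    "bp:optimal": -0.53363, "bp:high_normal": -0.06773,
    "bp:stage1": 0.26288, "bp:stage2_4": 0.46573,
    "diabetes": 0.59626, "smoking:current": 0.29246,
}
MEN_COEFS = {
    "age": 0.04826,
    "tc:<160": -0.65945, "tc:200-239": 0.17692, "tc:240-279": 0.50539, "tc:>=280": 0.65713,
    "hdl:<35": 0.49744, "hdl:35-44": 0.24310, "hdl:50-59": -0.05107, "hdl:>=60": -0.48660,
    "bp:optimal": -0.00226, "bp:high_normal": 0.28320,
    "bp:stage1": 0.52168, "bp:stage2_4": 0.61859,
    "diabetes": 0.42839, "smoking:current": 0.52337,
}

#: explicit (fixture-only) reference means: mid-life population, plain values
WOMEN_MEANS = {"age": 49.0, "age_sq": 2550.0, "diabetes": 0.05,
               **{t: 0.1 for t in WOMEN_COEFS if ":" in t}}
MEN_MEANS = {"age": 48.5, "diabetes": 0.05,
             **{t: 0.1 for t in MEN_COEFS if ":" in t}}


@pytest.fixture(scope="session")
def wilson_female() -> CoefficientSet:
    return CoefficientSet(sex="female", coefficients=dict(WOMEN_COEFS),
                          reference_means=dict(WOMEN_MEANS),
                          baseline_survival=BaselineSurvival(0.96246, 10.0, "cox_at_means"),
                          provenance="frs")


@pytest.fixture(scope="session")
def wilson_male() -> CoefficientSet:
    return CoefficientSet(sex="male", coefficients=dict(MEN_COEFS),
                          reference_means=dict(MEN_MEANS),
                          baseline_survival=BaselineSurvival(0.90015, 10.0, "cox_at_means"),
                          provenance="frs")


_DEFAULT_ROW = dict(age=72.0, sex="female", total_cholesterol=180.0,
                    hdl_cholesterol=52.0, sbp=124.0, dbp=82.0, diabetes=0,
                    smoking="never", time=8.0, event=0)


def make_cohort(rows: list[dict], horizon: float = 7.5) -> CohortTable:
    """Build a CohortTable from partial row dicts (defaults: reference-profile woman)."""
    if not rows:
        cols = {k: pd.Series(dtype=object if k in ("sex", "smoking") else float)
                for k in ("id", *list(_DEFAULT_ROW))}
        return CohortTable(pd.DataFrame(cols), horizon=horizon)
    full = []
    for i, row in enumerate(rows):
        r = dict(_DEFAULT_ROW)
        r.update(row)
        r.setdefault("id", f"p{i}")
        full.append(r)
    return CohortTable(pd.DataFrame(full), horizon=horizon)


@pytest.fixture
def cohort_factory():
    return make_cohort


def survival_cohort(times, events, horizon: float = 7.5, **overrides) -> CohortTable:
    """Cohort with given outcome vectors and constant risk factors."""
    rows = [dict(time=float(t), event=int(e), **overrides)
            for t, e in zip(times, events)]
    return make_cohort(rows, horizon=horizon)
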