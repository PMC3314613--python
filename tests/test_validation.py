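"""Harrell's C, bootstrap optimism, decile calibration and C comparison."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from chdrisk import (DomainError, FitError, compare_c, decile_ratio, harrell_c,
                     hl_cox, optimism_corrected_c)
from chdrisk.simulate import CohortSpec, generate

from conftest import make_cohort


# ---------- Harrell's C -------------------------------------------------------

def test_c_enumerated_example():
    res = harrell_c([2, 4, 6, 8], [1, 1, 1, 1], [0.9, 0.7, 0.8, 0.1])
    assert res.c == pytest.approx(5 / 6, abs=1e-12)
    assert res.n_usable_pairs == 6


def test_c_perfect_ranking_and_all_ties():
    t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
    e = np.ones(5)
    assert harrell_c(t, e, -t).c == 1.0
    assert harrell_c(t, e, np.zeros(5)).c == 0.5


def test_c_no_usable_pairs_errors():
    with pytest.raises(FitError):
        harrell_c([1.0, 2.0], [0, 0], [0.1, 0.2])


def c_oracle(times, events, scores):
    """All-pairs enumeration of the concordance rule."""
    conc = usable = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] > 0:
                usable += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / usable


def test_c_matches_enumeration_on_censored_data():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(5, 31))
        times = rng.exponential(1.0, n)
        events = rng.integers(0, 2, n).astype(float)
        scores = np.round(rng.uniform(size=n), 1)     # rounding forces score ties
        if not np.any(events[np.argsort(times)][:-1]):
            continue
        got = harrell_c(times, events, scores)
        assert got.c == pytest.approx(c_oracle(times, events, scores), abs=1e-12)


@given(st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True),
       st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
@settings(deadline=None, max_examples=60)
def test_c_invariant_under_increasing_transforms(scores, a, b):
    """C depends on scores only through ranks (why recalibration never changes it)."""
    scores = np.asarray(scores, dtype=float) / 10.0   # well-separated values
    rng = np.random.default_rng(0)
    n = scores.size
    times = np.arange(1.0, n + 1)
    events = np.ones(n)
    base = harrell_c(times, events, scores).c
    assert harrell_c(times, events, a * scores + b).c == base
    assert harrell_c(times, events, np.exp(scores)).c == base


# ---------- calibration chi-square -------------------------------------------

def test_hl_perfectly_matched_groups():
    # two risk strata, no censoring by t: observed counts equal expected exactly
    rows = []
    for k in range(5):
        rows.append({"time": 1.0 if k < 1 else 9.0, "event": 1 if k < 1 else 0})
    lo = [0.2] * 5
    for k in range(5):
        rows.append({"time": 1.0 if k < 2 else 9.0, "event": 1 if k < 2 else 0})
    hi = [0.4] * 5
    cohort = make_cohort(rows)
    res = hl_cox(np.array(lo + hi), cohort.df["time"], cohort.df["event"], 7.5, groups=2)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)
    assert res.df == 1


def test_hl_observed_reduces_to_counts_without_censoring():
    rng = np.random.default_rng(4)
    n = 200
    risks = rng.uniform(0.05, 0.6, n)
    events = (rng.uniform(size=n) < risks).astype(float)
    times = np.where(events > 0, rng.uniform(0.5, 7.0, n), 9.0)
    res = hl_cox(risks, times, events, 7.5)
    order = np.lexsort((np.arange(n), risks))
    counts = [events[g].sum() for g in np.array_split(order, 10)]
    assert np.allclose(res.table["observed"].to_numpy(), counts, atol=1e-9)
    assert res.df == 9


def test_hl_group_validation():
    with pytest.raises(DomainError):
        hl_cox([0.1, 0.2], [1, 2], [1, 0], 7.5, groups=0)
    with pytest.raises(DomainError):
        hl_cox([0.1, 0.2], [1, 2], [1, 0], 7.5, groups=5)


# ---------- decile ratios -----------------------------------------------------

def test_decile_ratio_scale_equivariance():
    rng = np.random.default_rng(9)
    n = 300
    risks = rng.uniform(0.01, 0.4, n)
    events = (rng.uniform(size=n) < 0.3).astype(float)
    times = np.where(events > 0, rng.uniform(0.5, 7.0, n), 9.0)
    base = decile_ratio(risks, times, events, 7.5)
    doubled = decile_ratio(np.clip(2 * risks, 0, 1), times, events, 7.5)
    assert doubled.loc["overall", "ratio"] == pytest.approx(
        2 * base.loc["overall", "ratio"], rel=1e-9)


def test_decile_ratio_single_group():
    out = decile_ratio([0.1, 0.2, 0.3], [1, 5, 9], [1, 0, 0], 7.5, groups=1)
    assert list(out.index) == ["1", "overall"]
    assert out.loc["1", "ratio"] == pytest.approx(out.loc["overall", "ratio"])


def test_decile_ratio_calibrated_simulation():
    """Risks taken from the true generating model give ratios near 1 everywhere."""
    spec = replace(CohortSpec(), n=6000, women_fraction=1.0, include_extended=False,
                   dropout_rate=0.0)
    cohort = generate(spec, seed=21)
    # true model risk: exponential hazard scaled by the centred linear predictor
    from chdrisk import linear_predictor, load_wilson
    from chdrisk.simulate import DEFAULT_LAMBDA0, expected_term_means
    cs = load_wilson("female")
    means = expected_term_means(spec, cs.terms)
    lbar = sum(cs.coefficients[t] * means[t] for t in cs.terms)
    eta = linear_predictor(cohort.df, cs) - lbar
    true_risk = 1 - np.exp(-DEFAULT_LAMBDA0["female"] * 7.5 * np.exp(eta))
    out = decile_ratio(true_risk, cohort.df["time"], cohort.df["event"], 7.5)
    assert out.loc["overall", "ratio"] == pytest.approx(1.0, abs=0.08)
    deciles = out.drop(index="overall")["ratio"].to_numpy(dtype=float)
    assert np.all(np.abs(deciles - 1.0) < 0.40)


def test_decile_ratio_zero_observed_marked_undefined():
    out = decile_ratio([0.1, 0.2], [9.0, 9.5], [0, 0], 7.5, groups=1)
    assert np.isnan(out.loc["overall", "ratio"])


# ---------- C comparison ------------------------------------------------------

def test_compare_c_identical_and_monotone_scores():
    rng = np.random.default_rng(14)
    n = 80
    times = rng.exponential(1.0, n)
    events = rng.integers(0, 2, n).astype(float)
    events[np.argmin(times)] = 1
    scores = rng.uniform(size=n)
    same = compare_c(times, events, scores, scores, B=50, seed=1)
    assert same["p"] == 1.0 and same["difference"] == 0.0
    mono = compare_c(times, events, scores, np.exp(3 * scores) + 2, B=50, seed=1)
    assert mono["p"] == 1.0 and mono["difference"] == 0.0


def test_compare_c_detects_informative_score():
    """Informative vs pure-noise score: the bootstrap test rejects in most runs."""
    rng = np.random.default_rng(6)
    wins = 0
    reps = 7
    for r in range(reps):
        n = 500
        x = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(0.8 * x))
        C = rng.uniform(0.2, 2.5, n)
        times, events = np.minimum(T, C), (T <= C).astype(float)
        noise = rng.normal(size=n)
        res = compare_c(times, events, x, noise, B=200, seed=100 + r)
        wins += res["p"] < 0.05
    assert wins > reps / 2


# ---------- bootstrap optimism -------------------------------------------------

@pytest.fixture(scope="module")
def small_cohort():
    spec = replace(CohortSpec(), n=60, women_fraction=1.0, include_extended=True)
    return generate(spec, seed=33)


def test_optimism_deterministic_given_seed(small_cohort):
    a = optimism_corrected_c(small_cohort, ("age", "diabetes"), B=20, seed=5)
    b = optimism_corrected_c(small_cohort, ("age", "diabetes"), B=20, seed=5)
    assert a.c == b.c and a.optimism == b.optimism


def test_optimism_positive_for_overfit_model(small_cohort):
    """Ten noise terms on n=60: corrected C must fall below apparent C."""
    rng = np.random.default_rng(17)
    df = small_cohort.df.copy()
    noise_cols = []
    for k in range(10):
        df[f"noise{k}"] = rng.normal(size=len(df))
        noise_cols.append(f"noise{k}")
    from chdrisk import CohortTable
    cohort = CohortTable(df, horizon=7.5)
    res = optimism_corrected_c(cohort, tuple(noise_cols), B=100, seed=2)
    assert res.optimism > 0
    assert res.c < res.apparent


def test_optimism_requires_positive_b(small_cohort):
    with pytest.raises(DomainError):
        optimism_corrected_c(small_cohort, ("age",), B=0, seed=1)
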