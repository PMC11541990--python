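"""Cohort-statistics tests: MBL classification boundaries, printed-fraction
rounding, odds-ratio estimators with an equivalence oracle, the Mann–Whitney
clone-size comparison, PRS arithmetic, and cross-validated AUC behavior."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mcakit.errors import ConfigurationError, InputError
from mcakit.simulate import simulate_association_cohort
from mcakit.stats import (
    Screen2x2,
    adjusted_or,
    classify_mbl,
    clone_size_test,
    crude_or,
    cv_predict_auc,
    percent,
    prevalence,
    prevalence_table,
    prs_score,
    screening_metrics,
)


# ---------------------------------------------------------------------------
# MBL classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pct,expected",
    [(0.0, "none"), (0.005, "lc_mbl"), (84.9, "lc_mbl"), (85.0, "hc_mbl"), (100.0, "hc_mbl")],
)
def test_classify_mbl_relative_boundaries(pct, expected):
    assert classify_mbl(clonal_b_pct=pct) == expected


@pytest.mark.parametrize(
    "count,expected",
    [(0, "none"), (499, "lc_mbl"), (500, "hc_mbl"), (5000, "hc_mbl")],
)
def test_classify_mbl_absolute_boundaries(count, expected):
    assert classify_mbl(clonal_b_count=count, rule="absolute") == expected


def test_classify_mbl_errors():
    with pytest.raises(InputError):
        classify_mbl(rule="absolute")  # no count
    with pytest.raises(InputError):
        classify_mbl(clonal_b_count=6000, rule="absolute")  # beyond MBL ceiling
    with pytest.raises(ConfigurationError):
        classify_mbl(clonal_b_pct=10, rule="fuzzy")


# ---------------------------------------------------------------------------
# prevalence / screening rounding (printed-table convention)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "carriers,n,expected",
    [
        (173, 332, 52.1),
        (8, 728, 1.1),
        (4, 2971, 0.1),
        (2967, 2971, 99.9),
        (325, 2170, 15.0),
        (41, 2462, 1.7),
        (0, 100, 0.0),
    ],
)
def test_prevalence_recomputes_printed_fractions(carriers, n, expected):
    assert prevalence(carriers, n) == (carriers, n, expected)


def test_percent_half_up_tie():
    assert percent(1, 8) == 12.5
    assert percent(125, 1000) == 12.5
    assert percent(1, 16) == 6.3  # 6.25 rounds half-up


def test_prevalence_zero_n_is_none():
    assert prevalence(0, 0)[2] is None


def test_prevalence_table_by_group():
    df = pd.DataFrame(
        {"group": ["a"] * 4 + ["b"] * 2, "flag": [True, True, False, False, True, False]}
    )
    out = prevalence_table(df, "flag").set_index("group")
    assert out.at["a", "percent"] == 50.0 and out.at["b", "carriers"] == 1


@pytest.mark.parametrize(
    "t,sens,spec",
    [
        (Screen2x2(tp=190, fp=54, fn=142, tn=3645), 57.2, 98.5),
        (Screen2x2(tp=0, fp=4, fn=0, tn=2967), None, 99.9),
    ],
)
def test_screening_metrics_printed_values(t, sens, spec):
    if sens is None:
        with pytest.warns(UserWarning):
            m = screening_metrics(t)
        assert m["sensitivity"] is None
    else:
        m = screening_metrics(t)
        assert m["sensitivity"] == sens
    assert m["specificity"] == spec


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def test_crude_or_unity_and_printed_counts():
    assert crude_or(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)
    res = crude_or(173, 159, 4, 2967)
    assert res.odds_ratio == pytest.approx(807.1, abs=0.1)  # 513291/636
    assert res.ci_low < res.odds_ratio < res.ci_high


def test_crude_or_zero_cell_flagged_nonfinite():
    res = crude_or(5, 0, 3, 10)
    assert not res.finite and np.isinf(res.odds_ratio)
    corrected = crude_or(5, 0, 3, 10, haldane=True)
    assert corrected.finite and np.isfinite(corrected.odds_ratio)


def test_adjusted_or_matches_crude_on_2x2():
    """With no covariates the logistic OR equals the cross-product OR."""
    a, b, c, d = 40, 60, 25, 75
    rows = (
        [(1, 1)] * a + [(0, 1)] * b + [(1, 0)] * c + [(0, 0)] * d
    )
    df = pd.DataFrame(rows, columns=["outcome", "exposure"])
    adj = adjusted_or(df, "outcome", "exposure")
    crude = crude_or(a, b, c, d)
    assert adj.odds_ratio == pytest.approx(crude.odds_ratio, rel=1e-3)
    assert adj.ci_low == pytest.approx(crude.ci_low, rel=1e-2)


def test_adjusted_or_null_coverage(rng):
    """Exposure independent of outcome: the 95% CI covers OR = 1 in most runs."""
    cover = 0
    for i in range(30):
        df = simulate_association_cohort(2000, exposure_or=1.0, seed=1000 + i)
        res = adjusted_or(df, "outcome", "exposure", ["age", "sex"])
        cover += res.ci_low <= 1.0 <= res.ci_high
    assert cover >= 26  # ~93% nominal over 30 draws


def test_separation_flag_when_exposure_only_in_cases():
    """Exposure absent from all controls (the del-17p situation) flags separation."""
    df = pd.DataFrame(
        {"outcome": [1] * 20 + [0] * 80, "exposure": [1] * 10 + [0] * 90}
    )
    res = adjusted_or(df, "outcome", "exposure")
    assert res.separation


# ---------------------------------------------------------------------------
# clone-size comparison
# ---------------------------------------------------------------------------

def test_clone_size_all_tied():
    out = clone_size_test([5.0] * 10, [5.0] * 10)
    assert out["p_value"] == 1.0 and out["U"] == 50.0


def test_clone_size_directionality(rng):
    a = rng.normal(10, 1, 200)
    b = rng.normal(8, 1, 200)
    out = clone_size_test(a, b)
    assert out["median_a"] > out["median_b"]
    assert out["p_value"] < 1e-6


def test_clone_size_equal_multisets_half_U():
    x = [1.0, 2.0, 3.0, 4.0]
    assert clone_size_test(x, list(x))["U"] == len(x) ** 2 / 2


def test_clone_size_null_p_uniform(rng):
    """Under H0 the two-sided p-values are ~Uniform(0,1) (KS check, seeded)."""
    ps = []
    for _ in range(100):
        ps.append(clone_size_test(rng.normal(0, 1, 100), rng.normal(0, 1, 100))["p_value"])
    assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def test_clone_size_empty_group_errors():
    with pytest.raises(InputError):
        clone_size_test([], [1.0])


# ---------------------------------------------------------------------------
# polygenic score
# ---------------------------------------------------------------------------

def test_prs_weighted_average_cases():
    assert prs_score([0.0] * 41, [1.0] * 41) == 0.0
    assert prs_score([1.0] * 41, [1.0] * 41) == pytest.approx(1.0)
    assert prs_score([2.0, 0.0], [1.0, 2.0]) == pytest.approx(2.0 / 3.0)


def test_prs_length_mismatch_and_range():
    with pytest.raises(InputError):
        prs_score([1.0, 1.0], [1.0])
    with pytest.raises(InputError):
        prs_score([3.0], [1.0])


def test_prs_mean_imputation():
    d = np.array([[2.0, np.nan], [0.0, 1.0], [2.0, 1.0]])
    scores = prs_score(d, [1.0, 1.0])
    # missing entry imputed with the per-SNP mean (1.0)
    assert scores[0] == pytest.approx((2.0 + 1.0) / 2.0)


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------

def test_cv_auc_null_is_half(rng):
    df = pd.DataFrame(
        {"outcome": rng.integers(0, 2, 3000), "x": rng.normal(0, 1, 3000)}
    )
    auc = cv_predict_auc(df, ["x"], seed=0)
    assert auc == pytest.approx(0.5, abs=0.03)


def test_cv_auc_perfect_separator():
    df = pd.DataFrame({"outcome": [0] * 100 + [1] * 100, "x": [0.0] * 100 + [1.0] * 100})
    assert cv_predict_auc(df, ["x"], seed=0) == 1.0


def test_cv_auc_invariant_to_monotone_transform(rng):
    n = 1000
    x = rng.lognormal(7.5, 0.5, n)
    p = 1 / (1 + np.exp(-(np.log(x) - 7.5)))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({"outcome": y, "alc": x, "log_alc": np.log(x)})
    a1 = cv_predict_auc(df, ["alc"], seed=3)
    a2 = cv_predict_auc(df, ["log_alc"], seed=3)
    assert a1 == pytest.approx(a2, abs=0.02)


def test_cv_auc_nested_models_not_better(rng):
    """In expectation a nested predictor set cannot beat its superset."""
    diffs = []
    for seed in range(6):
        df = simulate_association_cohort(2500, exposure_or=6.0, seed=seed)
        df["noise_free_signal"] = df["exposure"]
        small = cv_predict_auc(df, ["age"], seed=seed)
        big = cv_predict_auc(df, ["age", "exposure"], seed=seed)
        diffs.append(big - small)
    assert np.mean(diffs) > 0


def test_cv_auc_single_class_errors():
    df = pd.DataFrame({"outcome": [1] * 50, "x": np.arange(50.0)})
    with pytest.raises(InputError):
        cv_predict_auc(df, ["x"])
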