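"""Cohort-level statistics for mCA / MBL analyses.

MBL classification, prevalence cross-tabs with the printed-table
rounding convention (percent, half-up to one decimal), screening
sensitivity/specificity, crude (Woolf) and covariate-adjusted logistic
odds ratios with quasi-separation detection, the two-sided Mann–Whitney
clone-size comparison, polygenic-score computation, and stratified
10-fold cross-validated prediction AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, InputError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# MBL classification
# ---------------------------------------------------------------------------

def classify_mbl(
    clonal_b_pct: float | None = None,
    clonal_b_count: float | None = None,
    rule: str = "relative",
) -> str:
    """Classify MBL status as ``none`` / ``lc_mbl`` / ``hc_mbl``.

    ``relative`` rule (clone size relative to total B cells): no clone
    -> none; >= 85% -> hc_mbl; otherwise lc_mbl.  ``absolute`` rule
    (clonal B cells/uL): < 500 -> lc_mbl; 500–5000 -> hc_mbl; a count
    above 5000 cells/uL exceeds the MBL definition and raises.
    """
    if rule == "relative":
        if clonal_b_pct is None:
            raise InputError("relative rule requires clonal_b_pct")
        if clonal_b_pct < 0 or clonal_b_pct > 100:
            raise InputError(f"clonal_b_pct must be in [0, 100], got {clonal_b_pct}")
        if clonal_b_pct == 0:
            return "none"
        return "hc_mbl" if clonal_b_pct >= 85.0 else "lc_mbl"
    if rule == "absolute":
        if clonal_b_count is None:
            raise InputError("absolute rule requires clonal_b_count")
        if clonal_b_count < 0:
            raise InputError("clonal_b_count must be >= 0")
        if clonal_b_count == 0:
            return "none"
        if clonal_b_count < 500:
            return "lc_mbl"
        if clonal_b_count <= 5000:
            return "hc_mbl"
        raise InputError(
            f"clonal_b_count {clonal_b_count} exceeds the 5000 cells/uL MBL ceiling"
        )
    raise ConfigurationError(f"unknown MBL rule {rule!r}")


# ---------------------------------------------------------------------------
# prevalence and screening fractions (printed-table rounding)
# ---------------------------------------------------------------------------

def percent(carriers: int, n: int, ndigits: int = 1) -> float | None:
    """100*carriers/n rounded half-up to *ndigits* decimals; None when n = 0."""
    if n == 0:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(100 * carriers) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence(carriers: int, n: int) -> tuple[int, int, float | None]:
    """(carriers, n, percent) with the printed-table rounding convention."""
    if carriers < 0 or n < 0 or carriers > n:
        raise InputError(f"invalid counts carriers={carriers}, n={n}")
    return carriers, n, percent(carriers, n)


def prevalence_table(
    flags: pd.DataFrame, category: str, by: str = "group"
) -> pd.DataFrame:
    """Per-group carrier counts and percentages for one boolean flag column."""
    rows = []
    for group, sub in flags.groupby(by, sort=False):
        carriers = int(sub[category].sum())
        n = int(len(sub))
        rows.append({by: group, "carriers": carriers, "n": n, "percent": percent(carriers, n)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Screen2x2:
    """Screening-test contingency counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("contingency counts must be >= 0")


def screening_metrics(t: Screen2x2) -> dict:
    """Sensitivity and specificity as percentages rounded half-up to 1 decimal."""
    sens = percent(t.tp, t.tp + t.fn)
    spec = percent(t.tn, t.tn + t.fp)
    if sens is None or spec is None:
        warnings.warn("zero denominator in screening metrics", stacklevel=2)
    return {"sensitivity": sens, "specificity": spec}


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    finite: bool = True
    separation: bool = False
    converged: bool = True


def crude_or(a: int, b: int, c: int, d: int, haldane: bool = False) -> ORResult:
    """Unadjusted 2x2 odds ratio (a*d)/(b*c) with the Woolf 95% CI.

    Cells: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  ``haldane`` adds 0.5 to every cell when any
    cell is zero; without it a zero cell yields a non-finite OR flagged
    via ``finite=False``.
    """
    if min(a, b, c, d) < 0:
        raise InputError("counts must be >= 0")
    cells = [a, b, c, d]
    if 0 in cells:
        if haldane:
            cells = [x + 0.5 for x in cells]
        else:
            a_, b_, c_, d_ = cells
            or_ = np.inf if (b_ == 0 or c_ == 0) and a_ * d_ > 0 else 0.0
            return ORResult(or_, np.nan, np.nan, finite=False)
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return ORResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - Z95 * se)),
        ci_high=float(np.exp(np.log(or_) + Z95 * se)),
    )


def _design_matrix(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: categoricals to indicators, constant column added."""
    parts = []
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        elif s.dtype == bool:
            parts.append(s.astype(float))
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    # drop degenerate (constant) covariate columns
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    return sm.add_constant(X, has_constant="add")


def adjusted_or(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
) -> ORResult:
    """Covariate-adjusted odds ratio from a maximum-likelihood logistic fit.

    IRLS with convergence on deviance change < 1e-8, at most 100
    iterations; Wald 95% CI and p-value on the exposure coefficient.
    Quasi-separation (the exposure perfectly predicting one outcome
    arm, or a diverging coefficient) is reported via ``separation``.
    """
    y = df[outcome].astype(float)
    X = _design_matrix(df, [exposure, *covariates])
    if exposure not in X.columns:
        raise InputError(f"exposure {exposure!r} is degenerate in this data")
    # crosstab-based quasi-separation check on a binary exposure
    separation = False
    exp_vals = df[exposure].astype(float)
    if set(np.unique(exp_vals)) <= {0.0, 1.0}:
        tab = pd.crosstab(exp_vals, y)
        if tab.shape == (2, 2) and (tab.values == 0).any():
            separation = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
            converged = bool(res.converged)
        except Exception:
            return ORResult(np.nan, np.nan, np.nan, None, finite=False,
                            separation=True, converged=False)
    beta = float(res.params[exposure])
    se = float(res.bse[exposure])
    if abs(beta) > 15 or not np.isfinite(se):
        separation = True
    p = float(res.pvalues[exposure]) if np.isfinite(se) else None
    with np.errstate(over="ignore"):
        or_, lo, hi = np.exp([beta, beta - Z95 * se, beta + Z95 * se])
    return ORResult(
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        finite=np.isfinite(beta),
        separation=separation,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# clone-size comparison
# ---------------------------------------------------------------------------

def clone_size_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided Mann–Whitney U comparison of two clone-size distributions.

    Normal approximation with tie and continuity corrections; medians of
    both groups are reported.  Completely tied data gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"U": a.size * b.size / 2.0, "p_value": 1.0,
                "median_a": med_a, "median_b": med_b}
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"U": float(res.statistic), "p_value": float(res.pvalue),
            "median_a": med_a, "median_b": med_b}


# ---------------------------------------------------------------------------
# polygenic risk score
# ---------------------------------------------------------------------------

def prs_score(dosages, weights, impute_missing: bool = True):
    """Weighted-average polygenic score: sum(w*d) / sum(w).

    *dosages* is a length-m vector (one individual) or an (n, m) matrix;
    entries are allele dosages in [0, 2].  Missing dosages (NaN) are
    mean-imputed (per SNP for a matrix, over observed entries for a
    vector) when *impute_missing*; otherwise NaN propagates.
    """
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape[-1] != w.shape[0]:
        raise InputError(f"dosage length {d.shape[-1]} != weight length {w.shape[0]}")
    if np.nanmin(d) < 0 or np.nanmax(d) > 2:
        raise InputError("dosages must be in [0, 2]")
    if w.sum() == 0:
        raise InputError("weights must not sum to zero")
    if impute_missing and np.isnan(d).any():
        if d.ndim == 1:
            d = np.where(np.isnan(d), np.nanmean(d), d)
        else:
            col_mean = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d = d.copy()
            d[idx] = np.take(col_mean, idx[1])
    score = d @ w / w.sum()
    return float(score) if np.ndim(score) == 0 else score


# ---------------------------------------------------------------------------
# cross-validated prediction
# ---------------------------------------------------------------------------

#: predictor sets mirroring the HC-MBL detection models
MODEL_SPECS: dict[str, tuple[str, ...]] = {
    "alc": ("alc",),
    "mca": ("has_driver",),
    "demo_mca_prs": ("age", "sex", "has_driver", "prs"),
    "demo_mca_prs_alc": ("age", "sex", "has_driver", "prs", "alc"),
}


def cv_predict_auc(
    df: pd.DataFrame,
    features: Sequence[str],
    outcome: str = "outcome",
    k: int = 10,
    seed: int = 0,
) -> float:
    """Pooled out-of-fold AUC of a logistic model under stratified k-fold CV.

    Folds are stratified on the outcome and shuffled with *seed*; a
    logistic model is fit on each training split, out-of-fold predicted
    probabilities are pooled, and the AUC is the rank (Mann–Whitney)
    statistic of the pooled predictions.
    """
    y = df[outcome].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("outcome must have both classes")
    X = _design_matrix(df, list(features)).drop(columns="const").to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise InputError("a training fold contains a single outcome class")
        clf = LogisticRegression(C=1e10, max_iter=2000)  # effectively unpenalized
        clf.fit(X[train], y[train])
        oof[test] = clf.predict_proba(X[test])[:, 1]
    return float(roc_auc_score(y, oof))


def hc_mbl_prediction_aucs(
    cohort: pd.DataFrame, k: int = 10, seed: int = 0
) -> dict[str, float]:
    """Cross-validated AUCs of the four HC-MBL detection models.

    The outcome is HC-MBL versus the combined LC-MBL + no-MBL group
    (CLL/SLL rows are excluded); predictors per model follow
    :data:`MODEL_SPECS`.
    """
    sub = cohort[cohort["group"].isin(["none", "lc_mbl", "hc_mbl"])].copy()
    sub["outcome"] = (sub["group"] == "hc_mbl").astype(int)
    return {
        name: cv_predict_auc(sub, feats, "outcome", k=k, seed=seed)
        for name, feats in MODEL_SPECS.items()
    }
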