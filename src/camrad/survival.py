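"""Survival modelling and stratification of imaging features.

Univariate and multivariate Cox proportional-hazards models (per-SD hazard
ratios), correlation pruning before the multivariate fit, optimal log-rank
cutoff search with a transfer mode for fixed prior thresholds, Kaplan-Meier
curves, Harrell's concordance index and Benjamini-Hochberg FDR adjustment.
Model fitting is delegated to lifelines; the surface here standardises
inputs and reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "CutoffStratification",
    "cox_univariate",
    "multivariate_cox",
    "logrank_test",
    "optimal_cutoff",
    "km_curve",
    "concordance_index",
    "bh_adjust",
]


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    wald_stat: float
    p: float
    c_index: float


@dataclass
class CutoffStratification:
    threshold: float
    logrank_chi2: float
    logrank_p: float
    group_sizes: tuple[int, int]  # (low, high)
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    n_candidates: int  # number of cutoffs searched (optimism indicator)


def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    surv = pd.DataFrame({"time": np.asarray(surv["time"], float),
                         "event": np.asarray(surv["event"], int)})
    if np.any(surv["time"] <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(surv["event"])) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return surv


def cox_univariate(feature, surv: pd.DataFrame, standardize: bool = True) -> CoxFit:
    """Univariate Cox PH fit of one feature; HR is per SD when standardised.

    Raises on constant features or fewer than two events (non-identifiable).
    """
    surv = _check_surv(surv)
    x = np.asarray(feature, dtype=float)
    if x.std() <= 1e-12:
        raise ValueError("feature is constant; Cox model non-identifiable")
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    if standardize:
        x = (x - x.mean()) / x.std()
    df = surv.assign(x=x)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    lo = float(np.exp(beta - 1.959963984540054 * se))
    hi = float(np.exp(beta + 1.959963984540054 * se))
    c = concordance_index(beta * x, surv)
    return CoxFit(beta, se, float(np.exp(beta)), (lo, hi), (beta / se) ** 2, p, c)


def multivariate_cox(features: pd.DataFrame, surv: pd.DataFrame, prune_r: float = 0.7,
                     standardize: bool = True):
    """Correlation-pruned multivariate Cox fit.

    While any feature pair has |Pearson r| > ``prune_r``, the member with the
    larger univariate p value is dropped; the joint model is then fitted on
    the survivors.  Returns (per-feature CoxFit dict from the joint model,
    list of retained feature names).
    """
    surv = _check_surv(surv)
    feats = features.astype(float).copy()
    uni_p = {c: cox_univariate(feats[c], surv, standardize).p for c in feats.columns}
    retained = list(feats.columns)
    while len(retained) > 1:
        corr = feats[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= prune_r:
            break
        a, b = retained[i], retained[j]
        retained.remove(a if uni_p[a] >= uni_p[b] else b)
    X = feats[retained]
    if standardize:
        X = (X - X.mean()) / X.std()
    df = pd.concat([surv.reset_index(drop=True), X.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    risk = X.to_numpy() @ cph.params_[retained].to_numpy()
    c = concordance_index(risk, surv)
    fits = {}
    for name in retained:
        beta = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        lo = float(np.exp(beta - 1.959963984540054 * se))
        hi = float(np.exp(beta + 1.959963984540054 * se))
        fits[name] = CoxFit(beta, se, float(np.exp(beta)), (lo, hi), (beta / se) ** 2,
                            float(cph.summary.loc[name, "p"]), c)
    return fits, retained


def logrank_test(surv_a: pd.DataFrame, surv_b: pd.DataFrame):
    """One-degree-of-freedom log-rank test between two groups -> (chi2, p)."""
    a, b = _check_surv(surv_a), _check_surv(surv_b)
    time = np.concatenate([a["time"], b["time"]])
    event = np.concatenate([a["event"], b["event"]])
    group = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def km_curve(surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival) step table."""
    surv = _check_surv(surv)
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def concordance_index(risk, surv: pd.DataFrame) -> float:
    """Harrell's c: concordant / comparable pairs, risk ties scoring 0.5."""
    surv = _check_surv(surv)
    # lifelines' convention: higher score = longer predicted survival
    return float(_lifelines_cindex(surv["time"], -np.asarray(risk, float), surv["event"]))


def optimal_cutoff(feature, surv: pd.DataFrame, quantile_range=(0.1, 0.9),
                   threshold: float | None = None) -> CutoffStratification:
    """Log-rank-optimal dichotomisation of a feature (or transfer at a fixed one).

    Candidates are every distinct observed value inside the quantile window;
    the threshold with the smallest log-rank p is returned, ties taking the
    lower threshold.  Supplying ``threshold`` skips the search (transfer
    mode: a training-cohort threshold applied to a new cohort).
    """
    surv = _check_surv(surv)
    x = np.asarray(feature, dtype=float)

    def strat(t: float):
        low = x <= t
        if low.all() or not low.any():
            return None
        a = surv[low]
        b = surv[~low]
        chi2, p = logrank_test(a, b)
        return chi2, p, (int(low.sum()), int((~low).sum())), a, b

    if threshold is not None:
        res = strat(float(threshold))
        if res is None:
            raise ValueError("fixed threshold produces an empty group")
        chi2, p, sizes, a, b = res
        return CutoffStratification(float(threshold), chi2, p, sizes,
                                    km_curve(a), km_curve(b), 0)

    lo, hi = np.quantile(x, quantile_range)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    best = None
    n_valid = 0
    for t in candidates:
        res = strat(float(t))
        if res is None:
            continue
        n_valid += 1
        chi2, p, sizes, a, b = res
        if best is None or p < best[1]:
            best = (chi2, p, sizes, a, b, float(t))
    if best is None:
        raise ValueError("no candidate cutoff yields two non-empty groups")
    chi2, p, sizes, a, b, t = best
    return CutoffStratification(t, chi2, p, sizes, km_curve(a), km_curve(b), n_valid)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
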