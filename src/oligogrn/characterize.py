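"""Tumor characterization: reference-centroid correlation, survival, enrichment.

Tumors are compared to reference expression subtypes (e.g. the four glioma
expression classes or the CpG-island-methylator signature) by Pearson
correlation of per-tumor log2 expression ratios against class centroids.
Survival is summarized by the Kaplan-Meier product-limit estimator with
Greenwood 95% confidence intervals on the log-survival scale, and groups are
compared with the two-sample log-rank (Mantel-Cox) test.  Signature gene sets
are tested for annotation-category and pathway enrichment with one-sided
Fisher's exact tests, separately for up- and downregulated genes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "tumor_log_ratios",
    "centroid_correlate",
    "months_to_days",
    "km_estimate",
    "logrank_test",
    "fisher_enrichment",
]

#: months -> days conversion factor used in the clinical tables
DAYS_PER_MONTH = 30.4167


def tumor_log_ratios(
    tumors: pd.DataFrame, normals: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene tumor log2 expression minus the mean normal-brain expression.

    Genes absent from the normal reference are dropped with a warning.
    """
    if normals.shape[1] < 1:
        raise ValueError("need at least one normal sample")
    shared = tumors.index.intersection(normals.index)
    dropped = len(tumors.index) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} genes absent from normals dropped", stacklevel=2)
    return tumors.loc[shared].sub(normals.loc[shared].mean(axis=1), axis=0)


def centroid_correlate(
    ratios: pd.DataFrame, centroids: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every tumor against every reference centroid.

    ``ratios`` is genes x tumors; ``centroids`` is classes x genes (gene sets
    may differ by class — the correlation runs over the intersection, which
    must contain at least 3 genes).  Returns (r, p) DataFrames, tumors x
    classes; zero-variance profiles yield NaN.
    """
    r = pd.DataFrame(index=ratios.columns, columns=centroids.index, dtype=float)
    p = r.copy()
    for cls in centroids.index:
        cvec = centroids.loc[cls].dropna()
        shared = ratios.index.intersection(cvec.index)
        if len(shared) < 3:
            raise ValueError(f"class {cls!r} shares fewer than 3 genes with the data")
        c = cvec[shared].to_numpy(float)
        for tumor in ratios.columns:
            x = ratios.loc[shared, tumor].to_numpy(float)
            if np.std(x) == 0 or np.std(c) == 0:
                continue  # leave NaN
            res = stats.pearsonr(x, c)
            r.loc[tumor, cls] = res.statistic
            p.loc[tumor, cls] = res.pvalue
    return r, p


def months_to_days(months: float) -> int:
    """Convert survival months to integer days (factor 30.4167, round half
    away from zero)."""
    if months < 0:
        raise ValueError("months must be nonnegative")
    return int(np.floor(months * DAYS_PER_MONTH + 0.5))


def km_estimate(
    times: Sequence[float], events: Sequence[bool], *, alpha: float = 0.05
) -> pd.DataFrame:
    """Kaplan-Meier survival curve with Greenwood log-scale confidence bands.

    Returns a DataFrame indexed by event time with columns ``survival``,
    ``lower`` and ``upper``; the variance of log S(t) is the Greenwood sum
    ``sum d_i / (n_i (n_i - d_i))`` and the interval is
    ``S * exp(+- z * sqrt(var))``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if len(times) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    d = tab["observed"].to_numpy(float)
    n = tab["at_risk"].to_numpy(float)
    keep = d > 0
    t_ev = tab.index.to_numpy(float)[keep]
    frac = 1.0 - d[keep] / n[keep]
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d[keep] / (n[keep] * (n[keep] - d[keep]))
    var_log = np.cumsum(np.where(np.isfinite(gw_terms), gw_terms, np.inf))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(invalid="ignore", over="ignore"):
        lower = surv * np.exp(-z * np.sqrt(var_log))
        upper = np.minimum(surv * np.exp(z * np.sqrt(var_log)), 1.0)
    lower = np.where(surv > 0, lower, 0.0)
    upper = np.where(surv > 0, upper, 0.0)
    return pd.DataFrame(
        {"survival": surv, "lower": lower, "upper": upper},
        index=pd.Index(t_ev, name="time"),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test; returns (chi2 statistic, p).

    With no observed events in either group the test is undefined and
    (nan, nan) is returned with a warning.
    """
    events_a = np.asarray(events_a, bool)
    events_b = np.asarray(events_b, bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def fisher_enrichment(
    signature_by_direction: Mapping[str, set[str]],
    categories: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each category, per signature direction.

    The 2x2 table per (category, direction) crosses membership in the
    directional signature with membership in the category, within the tested
    universe.  Categories with no members in the universe are skipped.
    """
    rows = []
    for direction, sig in signature_by_direction.items():
        sig = sig & universe
        for name, cat in categories.items():
            cat = cat & universe
            if not cat:
                continue
            a = len(sig & cat)
            b = len(sig - cat)
            c = len(cat - sig)
            d = len(universe) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {
                    "category": name,
                    "direction": direction,
                    "n_overlap": a,
                    "n_category": len(cat),
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["category", "direction", "n_overlap", "n_category", "odds_ratio", "p"])
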