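"""RNA-seq normalization and moderated differential expression.

The normalization follows the precision-weighting approach for count data:
counts are transformed to log2 counts-per-million (prior count 0.5),
between-sample trends are removed by cyclic loess normalization, a gene-wise
mean-variance trend (lowess of sqrt residual SD against mean log count) is
fitted, and its inverse supplies per-observation precision weights.

Differential expression uses a weighted group-means linear model per gene
with empirical-Bayes variance moderation: gene-wise residual variances
``s_g^2`` with ``d_g`` degrees of freedom are shrunk toward a fitted
scaled-inverse-chi-square prior ``(s_0^2, d_0)``,

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),

and the moderated t statistic carries ``d_0 + d_g`` degrees of freedom.  The
prior is estimated by moment matching on the log-scale distribution of the
``s_g^2`` (the standard scaled-F estimator).  Multiple testing is controlled
by Benjamini-Hochberg q-values; the signature is the gene set with
``q < 0.01``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedExpression",
    "normalize",
    "moderated_test",
    "bh_adjust",
    "select_signature",
    "grade_comparison",
]


@dataclasses.dataclass
class NormalizedExpression:
    """Normalized log2-CPM with per-observation precision weights."""

    log_cpm: pd.DataFrame  # genes x samples
    weights: pd.DataFrame  # genes x samples, positive
    lib_size: pd.Series  # per sample
    n_filtered: int  # genes dropped by the expression filter

    def subset(self, samples: Sequence[str]) -> "NormalizedExpression":
        samples = list(samples)
        return NormalizedExpression(
            self.log_cpm[samples],
            self.weights[samples],
            self.lib_size[samples],
            self.n_filtered,
        )


# ---------------------------------------------------------------------------
# cyclic loess normalization


def _loess_adjust(m: np.ndarray, a: np.ndarray, span: float) -> np.ndarray:
    """Lowess fit of M on A, evaluated at every A (ends clamped)."""
    fit = lowess(m, a, frac=span, it=3, delta=0.01 * (a.max() - a.min()), return_sorted=True)
    return np.interp(a, fit[:, 0], fit[:, 1])


def _cyclic_loess(
    y: np.ndarray, *, method: str, span: float, cycles: int = 3
) -> np.ndarray:
    """Cyclic loess normalization of a genes x samples log-expression matrix.

    ``method="fast"`` normalizes each sample against the mean profile with
    the adjustments centered across samples (removing the common-mode
    component keeps repeated normalization stable); ``method="pairs"`` loops
    over all sample pairs, applying half the pairwise trend to each side.
    Loess normalization is not a projection, so the number of cycles is
    fixed rather than iterated to convergence.
    """
    y = y.copy()
    n = y.shape[1]
    for _ in range(cycles):
        if method == "fast":
            # abscissa is the fixed reference profile: regressing M on the
            # sample's own half-sum would share its noise and attenuate
            ref = y.mean(axis=1)
            F = np.column_stack([_loess_adjust(y[:, j] - ref, ref, span) for j in range(n)])
            y -= F - F.mean(axis=1, keepdims=True)
        elif method == "pairs":
            for j in range(n):
                for k in range(j + 1, n):
                    a = 0.5 * (y[:, j] + y[:, k])
                    f = _loess_adjust(y[:, j] - y[:, k], a, span)
                    y[:, j] -= f / 2
                    y[:, k] += f / 2
        else:
            raise ValueError(f"unknown cyclic loess method {method!r}")
    return y


def _group_design(samples: pd.Index, groups: pd.Series | None) -> np.ndarray:
    if groups is None:
        return np.ones((len(samples), 1))
    g = groups.reindex(samples)
    levels = pd.unique(g)
    return np.column_stack([(g == lev).to_numpy(float) for lev in levels])


def normalize(
    counts: pd.DataFrame,
    groups: pd.Series | None = None,
    *,
    method: str = "auto",
    span: float = 0.7,
    trend_span: float = 0.5,
    prior_count: float = 0.5,
    cpm_filter: float = 1.0,
    min_frac: float = 0.1,
) -> NormalizedExpression:
    """Transform raw counts into normalized log2-CPM with precision weights.

    Parameters
    ----------
    counts
        Nonnegative integer genes x samples matrix (tumors and normals
        together for a combined normalization).
    groups
        Optional sample -> group labels used for the mean-variance trend's
        group-means model (otherwise a single intercept is fitted).
    method
        Cyclic loess flavour: ``"pairs"`` (all sample pairs), ``"fast"``
        (against the mean profile), or ``"auto"`` (pairs up to 30 samples,
        fast above — the pairwise loop is quadratic in samples).
    cpm_filter, min_frac
        Keep genes with CPM above ``cpm_filter`` in at least ``min_frac`` of
        samples before normalization.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0).astype(float)
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm > cpm_filter).mean(axis=1) >= min_frac
    n_filtered = int((~keep).sum())
    counts = counts.loc[keep]

    y = np.log2((counts.to_numpy() + prior_count) / (lib.to_numpy() + 1.0)[None, :] * 1e6)
    if method == "auto":
        method = "pairs" if counts.shape[1] <= 30 else "fast"
    y = _cyclic_loess(y, method=method, span=span)

    # mean-variance trend on the normalized values
    design = _group_design(counts.columns, groups)
    coef, fitted, sigma, df_resid = _ols_fit(y, design)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib.to_numpy() + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=trend_span, it=3, return_sorted=True)
    fitted_logcount = fitted + (np.log2(lib.to_numpy() + 1.0) - np.log2(1e6))[None, :]
    sqrt_sd = np.interp(fitted_logcount, trend[:, 0], trend[:, 1])
    sqrt_sd = np.maximum(sqrt_sd, 1e-6)
    w = 1.0 / sqrt_sd**4

    idx, cols = counts.index, counts.columns
    return NormalizedExpression(
        log_cpm=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        lib_size=lib,
        n_filtered=n_filtered,
    )


def _ols_fit(y: np.ndarray, design: np.ndarray):
    """Row-wise unweighted least squares; returns (coef, fitted, sigma, df)."""
    q, r = np.linalg.qr(design)
    coef = np.linalg.solve(r, (y @ q).T).T
    fitted = coef @ design.T
    df = design.shape[0] - np.linalg.matrix_rank(design)
    resid = y - fitted
    rss = (resid**2).sum(axis=1)
    sigma = np.sqrt(rss / max(df, 1))  # residual SD; its sqrt enters the trend
    return coef, fitted, sigma, df


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to gene variances.

    Returns ``(d_0, s_0^2)``: the prior degrees of freedom and prior variance
    of the scaled-inverse-chi-square model for the true gene variances.
    ``d_0`` is ``inf`` when the observed variances are no more dispersed than
    chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink gene variances toward the fitted prior; returns (s2_post, d0, s0^2)."""
    d0, s0 = fit_f_dist(s2, df)
    if np.isinf(d0):
        post = np.full_like(np.asarray(s2, float), s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0, s0


# ---------------------------------------------------------------------------
# moderated two-group test


def moderated_test(
    norm: NormalizedExpression,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Weighted moderated t-test of group A versus group B per gene.

    Returns a DataFrame with ``log2_fc`` (A minus B), ``t``, ``p``, ``q``,
    ``s2_post`` and the shared ``d0``/``df_total`` in ``attrs``.
    ``d0_override`` forces the prior degrees of freedom (0 disables
    moderation; ``inf`` equalizes all variances) — mainly for limit-case
    checks.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    samples = group_a + group_b
    y = norm.log_cpm[samples].to_numpy()
    w = norm.weights[samples].to_numpy()
    na, nb = len(group_a), len(group_b)
    df_resid = na + nb - 2
    if df_resid < 1 and (d0_override is None or d0_override == 0):
        raise ValueError("no residual degrees of freedom and no prior to borrow from")

    wa, wb = w[:, :na], w[:, na:]
    ya, yb = y[:, :na], y[:, na:]
    swa, swb = wa.sum(axis=1), wb.sum(axis=1)
    mean_a = (wa * ya).sum(axis=1) / swa
    mean_b = (wb * yb).sum(axis=1) / swb
    fc = mean_a - mean_b
    stdev_unscaled = np.sqrt(1.0 / swa + 1.0 / swb)
    rss = (wa * (ya - mean_a[:, None]) ** 2).sum(axis=1) + (
        wb * (yb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / max(df_resid, 1)

    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            _, _, s0 = squeeze_var(s2, max(df_resid, 1))
            s2_post = np.full_like(s2, s0)
        elif d0 == 0:
            s2_post = s2
        else:
            _, _, s0 = squeeze_var(s2, max(df_resid, 1))
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post, d0, _ = squeeze_var(s2, df_resid)

    df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (stdev_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"log2_fc": fc, "t": t, "p": p, "s2_post": s2_post},
        index=norm.log_cpm.index,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["d0"] = float(d0)
    out.attrs["df_total"] = float(df_total) if not np.isinf(df_total) else np.inf
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH adjustment")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_signature(result: pd.DataFrame, q_cut: float = 0.01) -> pd.DataFrame:
    """Mark signature genes (q below the cut) and their direction in A vs B.

    Adds ``selected`` and ``direction`` columns; the fractions of up/down
    signature genes land in ``result.attrs``.
    """
    out = result.copy()
    out["selected"] = out["q"] < q_cut
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    n_sel = int(out["selected"].sum())
    out.attrs = dict(result.attrs)
    out.attrs["n_selected"] = n_sel
    out.attrs["frac_up"] = (
        float((out["selected"] & (out["direction"] == "up")).sum() / n_sel) if n_sel else 0.0
    )
    out.attrs["frac_down"] = 1.0 - out.attrs["frac_up"] if n_sel else 0.0
    return out


def grade_comparison(
    norm: NormalizedExpression,
    assignment: pd.DataFrame,
    clinical: pd.DataFrame,
    label: str,
    signature_genes: Sequence[str],
    *,
    q_cut: float = 0.01,
) -> pd.DataFrame:
    """Grade II vs III moderated test within one subgroup, signature genes only.

    The multiple-testing universe is restricted to the signature set, so the
    q-values answer "which signature genes also separate the grades".
    """
    members = assignment.index[
        (assignment["label"] == label) & (~assignment["excluded"].astype(bool))
    ]
    members = [m for m in members if m in norm.log_cpm.columns]
    grades = clinical.loc[members, "grade"]
    g2 = [m for m in members if grades[m] == "II"]
    g3 = [m for m in members if grades[m] == "III"]
    if not g2 or not g3:
        raise ValueError(f"subgroup {label!r} lacks one of the grades (II: {len(g2)}, III: {len(g3)})")
    sig = [g for g in signature_genes if g in norm.log_cpm.index]
    sub = NormalizedExpression(
        norm.log_cpm.loc[sig], norm.weights.loc[sig], norm.lib_size, norm.n_filtered
    )
    res = moderated_test(sub, g2, g3)
    return select_signature(res, q_cut)
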