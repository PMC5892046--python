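"""Benchmark computations: recovery, calibration and power studies.

Each function runs one self-contained study on synthetic data generated at
the study's stated conditions and returns the measured quantities.  These are
the computations behind the package's headline quality claims (subgroup
recovery, FDR control, covariance-test calibration, lasso-path correctness,
planted-network recovery, survival-test calibration) and are shared by the
test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .characterize import logrank_test
from .de import moderated_test, normalize, select_signature
from .grn import (
    CNV_PREDICTOR,
    consensus,
    covariance_test,
    cross_validate,
    estimate_sigma2,
    lasso_path_fit,
    validation_summary,
)
from .simulate import CohortConfig, generate_cohort, simulate_de_counts
from .subgroups import derive_subgroups

__all__ = [
    "subgroup_recovery",
    "de_fdr_power",
    "covariance_test_calibration",
    "lasso_oracle_deviation",
    "network_recovery",
    "logrank_calibration",
    "fista_lasso",
]


def subgroup_recovery(n_seeds: int = 20, *, seed: int = 0) -> dict:
    """ARI between recovered and planted subgroups on default cohorts
    (193 tumors, arm shifts +-0.5, observed copy-number noise SD 0.3)."""
    aris = []
    for s in range(n_seeds):
        cohort = generate_cohort(CohortConfig(seed=seed + s), with_expression=False)
        assignment, _, _ = derive_subgroups(
            cohort.cnv, cohort.annotation, cohort.clinical
        )
        kept = assignment[~assignment["excluded"]]
        aris.append(
            adjusted_rand_score(
                cohort.truth.true_subgroup[kept.index], kept["cluster"].astype(int)
            )
        )
    return {"min_ari": float(np.min(aris)), "mean_ari": float(np.mean(aris))}


def de_fdr_power(
    n_seeds: int = 3,
    *,
    n_genes: int = 2000,
    n_a: int = 60,
    n_b: int = 40,
    frac_de: float = 0.1,
    lfc: float = 1.0,
    q_cut: float = 0.01,
    seed: int = 0,
) -> dict:
    """Empirical FDR and power of the moderated-test signature selection on
    two-group cohorts with a planted non-null fraction."""
    v = r = tp = n_true = 0
    for s in range(n_seeds):
        counts, groups, truth = simulate_de_counts(
            n_genes=n_genes, n_a=n_a, n_b=n_b, frac_de=frac_de, lfc=lfc, seed=seed + s
        )
        norm = normalize(counts, groups)
        a = list(groups.index[groups == "A"])
        b = list(groups.index[groups == "B"])
        res = select_signature(moderated_test(norm, a, b), q_cut)
        sel = set(res.index[res["selected"]])
        true_de = {g for g, _d in truth}
        tp += len(sel & true_de)
        v += len(sel - true_de)
        r += len(sel)
        n_true += len(true_de)
    return {
        "fdr": v / max(r, 1),
        "power": tp / max(n_true, 1),
    }


def covariance_test_calibration(
    reps: int = 2000, *, n: int = 100, p: int = 10, seed: int = 0
) -> dict:
    """First-entry covariance-test statistic under the global null, against
    its Exp(1) asymptotic reference."""
    rng = np.random.default_rng(seed)
    t1 = np.empty(reps)
    for i in range(reps):
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=n)
        y -= y.mean()
        path = lasso_path_fit(X, y, max_steps=max(p + 2, 12))
        sigma2 = estimate_sigma2(X, y, path)
        t1[i] = covariance_test(path, X, y, sigma2)[0][2]
    ks = stats.kstest(t1, "expon")
    return {"mean_T1": float(t1.mean()), "ks_p": float(ks.pvalue)}


def fista_lasso(
    X: np.ndarray, y: np.ndarray, alpha: float, *, max_iter: int = 200_000, tol: float = 1e-14
) -> np.ndarray:
    """Independent proximal-gradient (FISTA) solver of
    ``(1/2n)||y - Xb||^2 + alpha ||b||_1`` — the generic convex oracle used
    to verify the LARS path knots."""
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n
    b = np.zeros(p)
    z = b.copy()
    t = 1.0
    for _ in range(max_iter):
        g = X.T @ (X @ z - y) / n
        b_new = z - g / L
        b_new = np.sign(b_new) * np.maximum(np.abs(b_new) - alpha / L, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = b_new + (t - 1) / t_new * (b_new - b)
        if np.abs(b_new - b).max() < tol:
            return b_new
        b, t = b_new, t_new
    return b


def lasso_oracle_deviation(
    n_problems: int = 50, *, n: int = 50, p: int = 10, seed: int = 0
) -> dict:
    """Largest deviation between LARS-path knot solutions and the convex
    oracle across random problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        beta = np.zeros(p)
        beta[: p // 3] = rng.normal(0, 2, p // 3)
        y = X @ beta + rng.normal(size=n)
        y -= y.mean()
        path = lasso_path_fit(X, y)
        for k in range(1, path.n_knots):
            b = fista_lasso(X, y, path.alphas[k])
            worst = max(worst, float(np.abs(b - path.coefs[:, k]).max()))
    return {"max_abs_deviation": worst}


def network_recovery(
    *,
    n_genes: int = 500,
    n_tfs: int = 50,
    n_samples: tuple[int, int, int] = (100, 50, 0),
    n_iter: int = 100,
    freq: float = 0.75,
    alpha: float = 5e-5,
    seed: int = 0,
) -> dict:
    """Planted-network recovery and the two-design prediction comparison.

    Generates a reduced-scale cohort, infers both the copy-number-only and
    the copy-number-plus-TF-expression consensus networks with repeated
    subsampling, and scores retained links against the planted truth.
    """
    cfg = CohortConfig(
        n_per_subgroup=n_samples, n_genes=n_genes, n_tfs=n_tfs, seed=seed
    )
    cohort = generate_cohort(cfg)
    norm = normalize(cohort.counts)
    tumors = cohort.tumor_ids
    expr = norm.log_cpm[tumors]
    responses = list(expr.index)
    tfs = [g for g in cohort.annotation.tf_genes() if g in expr.index]
    cnv = cohort.cnv.loc[responses, tumors]

    res_full = cross_validate(
        expr, cnv, responses, tfs, mode="cnv+exp", n_iter=n_iter, alpha=alpha, seed=seed
    )
    res_cnv = cross_validate(
        expr, cnv, responses, tfs, mode="cnv", n_iter=n_iter, alpha=alpha, seed=seed
    )
    net = consensus(res_full, freq)
    got = {
        (pred, resp): s
        for pred, resp, s, _c in net.retained_links()
        if pred != CNV_PREDICTOR
    }
    truth = {
        (tf, tgt): s
        for tf, tgt, s, _e in cohort.truth.true_links
        if tf in set(tfs) and tgt in set(responses)
    }
    tp = len(set(got) & set(truth))
    val_full = validation_summary(res_full)
    val_cnv = validation_summary(res_cnv)
    u = stats.mannwhitneyu(
        val_full.per_gene.dropna(), val_cnv.per_gene.dropna(), alternative="greater"
    )
    sign_match = sum(1 for k in set(got) & set(truth) if got[k] == truth[k])
    return {
        "precision": tp / max(len(got), 1),
        "recall": tp / max(len(truth), 1),
        "sign_accuracy": sign_match / max(tp, 1),
        "median_r_cnv_exp": val_full.median_correlation,
        "median_r_cnv": val_cnv.median_correlation,
        "median_gain": val_full.median_correlation - val_cnv.median_correlation,
        "ranksum_p": float(u.pvalue),
        "frac_never_modeled_cnv": val_cnv.n_never_modeled / len(responses),
    }


def logrank_calibration(
    null_reps: int = 1000,
    power_reps: int = 100,
    *,
    n: int = 100,
    n_power: int = 200,
    hazard_ratio: float = 3.0,
    seed: int = 0,
) -> dict:
    """Type-I error under equal hazards and power under a strong hazard
    ratio for the two-group log-rank test."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(null_reps):
        ta, tb = rng.exponential(100, n), rng.exponential(100, n)
        ca, cb = rng.exponential(300, n), rng.exponential(300, n)
        _, p = logrank_test(
            np.minimum(ta, ca), ta <= ca, np.minimum(tb, cb), tb <= cb
        )
        rej += p < 0.05
    type1 = rej / null_reps
    rej = 0
    for _ in range(power_reps):
        ta = rng.exponential(100, n_power)
        tb = rng.exponential(100 * hazard_ratio, n_power)
        _, p = logrank_test(ta, np.ones(n_power, bool), tb, np.ones(n_power, bool))
        rej += p < 0.05
    return {"type1_error": type1, "power": rej / power_reps}
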