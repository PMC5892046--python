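"""Signature-specific gene regulatory network inference.

For every signature gene a sparse linear model of its normalized expression
is fitted by LARS-lasso over one of two predictor designs:

* ``cnv``      — only the gene's own copy-number log-ratio (one predictor);
* ``cnv+exp``  — the copy number plus the expression of every signature
  transcription factor, excluding the response gene's own expression when it
  is itself a TF.

Predictors entering the lasso path are screened sequentially with the
covariance test: for the k-th entering predictor, with path knots
``lam_1 > lam_2 > ...`` and active set A just before the entry,

    T_k = ( <y, X b(lam_{k+1})> - <y, X_A b_A(lam_{k+1})> ) / sigma^2 ,

which is asymptotically Exp(1) under the null that all signal variables are
already in A.  The per-predictor p-value is ``exp(-T_k)``; the path is
traversed until the first entry with p at or above the significance cut
(default 5e-5), and the model is the lasso solution at the knot after the
last significant entry.  An empty model is a valid outcome ("no prediction"
for that gene).

Each network is validated by repeated random subsampling: 100 random
two-thirds/one-third train/test splits, models refit per split, test-set
expression predicted, and per-gene Pearson correlations recorded.  The
consensus network keeps links selected in at least 75% of iterations; the
sign of a kept link is the majority coefficient sign across its presences
(minority shares of 25% or more are flagged as sign conflicts).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path

__all__ = [
    "LassoPath",
    "lasso_path",
    "covariance_test",
    "fit_gene_model",
    "build_design",
    "cross_validate",
    "consensus",
    "validation_summary",
    "hub_analysis",
    "family_signature",
    "CrossValidationResult",
    "RegulatoryNetwork",
    "ValidationReport",
    "CNV_PREDICTOR",
]

#: name of the gene-specific copy-number predictor column
CNV_PREDICTOR = "CNV"


# ---------------------------------------------------------------------------
# lasso path


@dataclasses.dataclass
class LassoPath:
    """Piecewise-linear LARS-lasso coefficient path.

    ``alphas`` are the knot penalty values (decreasing, in the 1/(2n) RSS
    convention), ``coefs`` the p x n_knots coefficient matrix at the knots.
    Solutions between knots are linear interpolations.
    """

    alphas: np.ndarray
    coefs: np.ndarray

    @property
    def n_knots(self) -> int:
        return len(self.alphas)

    def support(self, knot: int) -> set[int]:
        return set(np.flatnonzero(self.coefs[:, knot] != 0.0))

    def solution_at(self, alpha: float) -> np.ndarray:
        """Lasso coefficients at an arbitrary penalty by interpolation."""
        if self.n_knots == 0:
            raise ValueError("empty path")
        if alpha >= self.alphas[0]:
            return np.zeros(self.coefs.shape[0])
        # np.interp needs increasing x
        rev_a = self.alphas[::-1]
        return np.array(
            [np.interp(alpha, rev_a, self.coefs[j, ::-1]) for j in range(self.coefs.shape[0])]
        )

    def entry_events(self) -> list[tuple[int, int]]:
        """(knot index, predictor index) for each variable-entry event.

        The entering variable has zero coefficient at its entry knot and a
        nonzero one at the next knot.
        """
        events = []
        for k in range(self.n_knots - 1):
            new = self.support(k + 1) - self.support(k)
            for j in sorted(new):
                events.append((k, j))
        return events


def lasso_path_fit(X: np.ndarray, y: np.ndarray, *, max_steps: int = 50) -> LassoPath:
    """Compute the LARS-lasso path (with drop events) for standardized X,
    centered y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.size == 0 or not np.any(X):
        return LassoPath(np.array([]), np.zeros((X.shape[1] if X.ndim == 2 else 0, 0)))
    alphas, _, coefs = lars_path(X, y, method="lasso", max_iter=max_steps)
    return LassoPath(alphas, coefs)


# public alias matching the operation name
lasso_path = lasso_path_fit


# ---------------------------------------------------------------------------
# covariance test


def estimate_sigma2(X: np.ndarray, y: np.ndarray, path: LassoPath) -> float:
    """Error-variance estimate for the covariance test.

    Full-model OLS residual variance when ``n > p + 1``; otherwise (the
    n << p regime of TF designs) the residual variance at the last path knot
    with its active-set degrees of freedom.
    """
    n, p = X.shape
    if n > p + 1:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid / (n - p - 1))
    if path.n_knots == 0:
        raise ValueError("cannot estimate sigma^2 from an empty path")
    beta = path.coefs[:, -1]
    k = int(np.count_nonzero(beta))
    df = max(n - k - 1, 1)
    resid = y - X @ beta
    return float(resid @ resid / df)


def _covariance_test_iter(path: LassoPath, X: np.ndarray, y: np.ndarray, sigma2: float):
    """Yield covariance-test events lazily (knot, predictor, T, p)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    for knot, j in path.entry_events():
        lam_next = path.alphas[knot + 1]
        beta_full = path.coefs[:, knot + 1]
        fit_full = float(y @ (X @ beta_full))
        active_before = sorted(path.support(knot))
        if active_before:
            sub = lasso_path_fit(X[:, active_before], y, max_steps=50)
            beta_sub = sub.solution_at(lam_next)
            fit_sub = float(y @ (X[:, active_before] @ beta_sub))
        else:
            fit_sub = 0.0
        T = (fit_full - fit_sub) / sigma2
        p = float(np.clip(np.exp(-max(T, 0.0)), np.nextafter(0, 1), 1.0))
        yield (knot, j, float(T), p)


def covariance_test(
    path: LassoPath, X: np.ndarray, y: np.ndarray, sigma2: float
) -> list[tuple[int, int, float, float]]:
    """Sequential covariance-test p-values along the path.

    Returns, per variable-entry event in path order, tuples
    ``(knot, predictor, T, p)`` with ``p = exp(-T)`` clipped into (0, 1].
    """
    return list(_covariance_test_iter(path, X, y, sigma2))


def fit_gene_model(
    X: np.ndarray,
    y: np.ndarray,
    *,
    alpha: float = 5e-5,
    max_steps: int = 20,
    sigma2: float | None = None,
) -> np.ndarray | None:
    """Sequentially screened lasso fit for one response.

    ``X`` must be standardized and ``y`` centered.  The path is traversed in
    entry order until the first covariance-test p at or above ``alpha``; the
    returned coefficients are the path solution at the knot after the last
    significant entry.  Returns ``None`` when no entry is significant.
    """
    path = lasso_path_fit(X, y, max_steps=max_steps)
    if path.n_knots < 2:
        return None
    if sigma2 is None:
        sigma2 = estimate_sigma2(X, y, path)
    if sigma2 <= 0:
        return None
    last_knot = None
    for knot, _j, _T, p in _covariance_test_iter(path, X, y, sigma2):
        if p < alpha:
            last_knot = knot
        else:
            break
    if last_knot is None:
        return None
    return path.coefs[:, last_knot + 1].copy()


# ---------------------------------------------------------------------------
# predictor designs


@dataclasses.dataclass
class PredictorDesign:
    """Predictor bookkeeping for one response gene."""

    response: str
    predictors: list[str]  # CNV_PREDICTOR plus TF gene names
    mode: str  # "cnv" or "cnv+exp"


def build_design(
    response: str,
    tfs: Sequence[str],
    mode: str,
) -> PredictorDesign:
    """Predictor list for a response: its own copy number, plus (in
    ``cnv+exp`` mode) every signature TF's expression except its own."""
    if mode == "cnv":
        preds = [CNV_PREDICTOR]
    elif mode == "cnv+exp":
        preds = [CNV_PREDICTOR] + [t for t in tfs if t != response]
    else:
        raise ValueError(f"unknown design mode {mode!r}")
    return PredictorDesign(response, preds, mode)


# ---------------------------------------------------------------------------
# subsampling cross-validation


@dataclasses.dataclass
class CrossValidationResult:
    """Link presences and test correlations across subsampling iterations."""

    pos_counts: pd.DataFrame  # responses x predictors
    neg_counts: pd.DataFrame
    corr: pd.DataFrame  # responses x iterations, NaN = no model that iteration
    n_iter: int
    mode: str
    mean_test_size: float


def _standardize(train: np.ndarray, test: np.ndarray | None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dead = sd == 0
    sd = np.where(dead, 1.0, sd)
    tr = (train - mu) / sd
    tr[:, dead] = 0.0
    te = None
    if test is not None:
        te = (test - mu) / sd
        te[:, dead] = 0.0
    return tr, te, dead


def cross_validate(
    expr: pd.DataFrame,
    cnv: pd.DataFrame,
    responses: Sequence[str],
    tfs: Sequence[str],
    *,
    mode: str = "cnv+exp",
    n_iter: int = 100,
    train_frac: float = 2.0 / 3.0,
    alpha: float = 5e-5,
    max_steps: int = 20,
    seed: int = 0,
) -> CrossValidationResult:
    """Repeated random-subsampling network inference.

    ``expr`` is normalized log expression of the signature genes x tumors and
    ``cnv`` their copy-number log ratios on the same samples.  Each iteration
    draws a ``train_frac`` training split (without replacement), standardizes
    predictors on the training samples only, fits the screened lasso per
    response, predicts the held-out samples and records link presences with
    their coefficient signs.  Iteration RNG streams are spawned from the
    master seed, so results are independent of sample ordering given the same
    split indices.
    """
    responses = list(responses)
    tfs = [t for t in tfs if t in expr.index]
    samples = list(expr.columns)
    n = len(samples)
    if n < 6:
        raise ValueError("need at least 6 samples for 2/3 - 1/3 splits")
    n_train = int(np.floor(train_frac * n))
    if n_train < 3 or n - n_train < 1:
        raise ValueError("degenerate train/test split")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    predictors = ([CNV_PREDICTOR] + tfs) if mode == "cnv+exp" else [CNV_PREDICTOR]
    pos = np.zeros((len(responses), len(predictors)), dtype=np.int32)
    neg = np.zeros_like(pos)
    corr = np.full((len(responses), n_iter), np.nan)
    pred_index = {p: i for i, p in enumerate(predictors)}
    tf_col = {t: j for j, t in enumerate(tfs)}

    expr_arr = expr.to_numpy()
    expr_row = {g: i for i, g in enumerate(expr.index)}
    cnv_arr = cnv.reindex(index=responses, columns=samples).to_numpy()

    # splits are drawn over the lexicographically sorted sample ids, so the
    # ensemble is invariant to the column order of the input matrices
    col_pos = {s: i for i, s in enumerate(samples)}
    sorted_pos = np.array([col_pos[s] for s in sorted(samples)])

    streams = np.random.SeedSequence(seed).spawn(n_iter)
    test_sizes = []
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        perm = sorted_pos[rng.permutation(n)]
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        test_sizes.append(len(test_idx))

        if mode == "cnv+exp":
            tf_block = expr_arr[[expr_row[t] for t in tfs]].T  # samples x TFs
            tf_train, tf_test, _ = _standardize(tf_block[train_idx], tf_block[test_idx])
        for ri, response in enumerate(responses):
            yfull = expr_arr[expr_row[response]]
            y_train = yfull[train_idx]
            y_test = yfull[test_idx]
            ybar = y_train.mean()

            cnv_col = cnv_arr[ri][:, None]
            c_train, c_test, _ = _standardize(cnv_col[train_idx], cnv_col[test_idx])
            if mode == "cnv+exp":
                X_train = np.concatenate([c_train, tf_train], axis=1)
                X_test = np.concatenate([c_test, tf_test], axis=1)
                names = [CNV_PREDICTOR] + tfs
                if response in tf_col:  # self-expression never predicts itself
                    drop = 1 + tf_col[response]
                    keep = [j for j in range(X_train.shape[1]) if j != drop]
                    X_train, X_test = X_train[:, keep], X_test[:, keep]
                    names = [names[j] for j in keep]
            else:
                X_train, X_test, names = c_train, c_test, [CNV_PREDICTOR]

            beta = fit_gene_model(
                X_train, y_train - ybar, alpha=alpha, max_steps=max_steps
            )
            if beta is None or not np.any(beta):
                continue
            nz = np.flatnonzero(beta)
            for j in nz:
                col = pred_index[names[j]]
                if beta[j] > 0:
                    pos[ri, col] += 1
                else:
                    neg[ri, col] += 1
            y_hat = X_test @ beta + ybar
            if np.std(y_hat) > 0 and np.std(y_test) > 0:
                corr[ri, it] = np.corrcoef(y_hat, y_test)[0, 1]
            # constant prediction or response: correlation undefined, left NaN

    return CrossValidationResult(
        pos_counts=pd.DataFrame(pos, index=responses, columns=predictors),
        neg_counts=pd.DataFrame(neg, index=responses, columns=predictors),
        corr=pd.DataFrame(corr, index=responses, columns=range(n_iter)),
        n_iter=n_iter,
        mode=mode,
        mean_test_size=float(np.mean(test_sizes)),
    )


# ---------------------------------------------------------------------------
# consensus network


@dataclasses.dataclass
class RegulatoryNetwork:
    """Signed consensus link counts and the retained link set."""

    counts: pd.DataFrame  # signed: majority sign x presence count
    retained: pd.DataFrame  # bool
    conflicts: pd.DataFrame  # bool: minority sign share >= 25% of presences
    n_iterations: int
    freq: float

    def retained_links(self) -> list[tuple[str, str, int, int]]:
        """(predictor, response, sign, presence count) for every kept link."""
        links = []
        arr = self.retained.to_numpy()
        for ri, ci in zip(*np.nonzero(arr)):
            cnt = int(self.counts.iat[ri, ci])
            links.append(
                (
                    self.counts.columns[ci],
                    self.counts.index[ri],
                    1 if cnt > 0 else -1,
                    abs(cnt),
                )
            )
        return links

    def out_degrees(self) -> pd.Series:
        """Retained out-degree per TF predictor (copy-number column excluded)."""
        tf_cols = [c for c in self.counts.columns if c != CNV_PREDICTOR]
        return self.retained[tf_cols].sum(axis=0).astype(int)


def consensus(ensemble: CrossValidationResult, freq: float = 0.75) -> RegulatoryNetwork:
    """Keep links present in at least ``freq`` of the subsampling iterations.

    The stored cell value is the presence count signed by the majority
    coefficient sign; retention depends on unsigned presence only.
    """
    pos = ensemble.pos_counts.to_numpy()
    neg = ensemble.neg_counts.to_numpy()
    presence = pos + neg
    need = int(np.ceil(freq * ensemble.n_iter))
    retained = presence >= need
    sign = np.where(pos >= neg, 1, -1)
    counts = sign * presence
    with np.errstate(invalid="ignore", divide="ignore"):
        minority = np.minimum(pos, neg) / np.where(presence > 0, presence, 1)
    conflicts = (minority >= 0.25) & (presence > 0)
    idx, cols = ensemble.pos_counts.index, ensemble.pos_counts.columns
    return RegulatoryNetwork(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        retained=pd.DataFrame(retained, index=idx, columns=cols),
        conflicts=pd.DataFrame(conflicts, index=idx, columns=cols),
        n_iterations=ensemble.n_iter,
        freq=freq,
    )


# ---------------------------------------------------------------------------
# validation report


@dataclasses.dataclass
class ValidationReport:
    """Prediction-accuracy summary across subsampling iterations."""

    per_gene: pd.Series  # mean test correlation per response (NaN = never modeled)
    median_correlation: float
    frac_significant: float  # fraction of modeled genes with correlation p < 0.05
    n_never_modeled: int


def validation_summary(ensemble: CrossValidationResult, *, p_cut: float = 0.05) -> ValidationReport:
    """Per-gene mean test correlation, median over modeled genes, and the
    fraction of modeled genes whose mean correlation is individually
    significant (t transform at the mean test-set size)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        per_gene = ensemble.corr.mean(axis=1, skipna=True)
    modeled = per_gene.dropna()
    never = int(per_gene.isna().sum())
    if modeled.empty:
        return ValidationReport(per_gene, float("nan"), 0.0, never)
    m = ensemble.mean_test_size
    r = modeled.clip(-0.999999, 0.999999)
    with np.errstate(invalid="ignore"):
        tstat = r * np.sqrt(max(m - 2.0, 1.0) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), max(m - 2.0, 1.0))
    return ValidationReport(
        per_gene=per_gene,
        median_correlation=float(modeled.median()),
        frac_significant=float((p < p_cut).mean()),
        n_never_modeled=never,
    )


# ---------------------------------------------------------------------------
# hubs, modules, gene families


def _retained_graph(net: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for pred, resp, sign, count in net.retained_links():
        if pred == CNV_PREDICTOR:
            continue  # copy-number links are not TF->gene edges
        g.add_edge(pred, resp, sign=sign, count=count)
    return g


def hub_analysis(
    net: RegulatoryNetwork, min_out: int = 10
) -> tuple[list[str], nx.DiGraph, list[set[str]]]:
    """Hub TFs, the hub-centred subnetwork, and its modules.

    Hubs are TFs with retained out-degree at or above ``min_out``.  The
    subnetwork keeps the hubs plus every signature gene linked to a hub by an
    ingoing or outgoing retained link; modules are the connected components
    of its undirected projection.
    """
    degrees = net.out_degrees()
    hubs = sorted(degrees.index[degrees >= min_out])
    full = _retained_graph(net)
    nodes = set(hubs)
    edges = []
    for u, v, data in full.edges(data=True):
        if u in hubs or v in hubs:
            nodes.update((u, v))
            edges.append((u, v, data))
    sub = nx.DiGraph()
    sub.add_nodes_from(nodes)
    for u, v, data in edges:
        sub.add_edge(u, v, **data)
    modules = [set(c) for c in nx.connected_components(sub.to_undirected())]
    modules.sort(key=lambda c: (-len(c), sorted(c)[0] if c else ""))
    return hubs, sub, modules


def family_signature(
    net: RegulatoryNetwork,
    fold_changes: pd.Series,
    prefixes: Sequence[str] = ("HOX", "SOX"),
) -> pd.DataFrame:
    """Subgroup fold-change table of gene-family members present in the network.

    A gene is "in the network" if it participates in at least one retained
    link (as predictor or response).  ``fold_changes`` maps gene -> mean log2
    expression difference between the two compared subgroups.
    """
    in_net: set[str] = set()
    for pred, resp, _s, _c in net.retained_links():
        if pred != CNV_PREDICTOR:
            in_net.add(pred)
        in_net.add(resp)
    rows = []
    for gene in sorted(in_net):
        for prefix in prefixes:
            if gene.startswith(prefix):
                fc = float(fold_changes.get(gene, np.nan))
                rows.append(
                    {
                        "gene": gene,
                        "family": prefix,
                        "log2_fc": fc,
                        "direction": "up" if fc > 0 else "down",
                    }
                )
    out = pd.DataFrame(rows, columns=["gene", "family", "log2_fc", "direction"])
    if out.empty:
        warnings.warn("no family member present in the network", stacklevel=2)
    return out
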