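"""Copy-number-based molecular subgrouping.

Tumors are clustered on their genome-wide copy-number log-ratio profiles
(Euclidean distance, complete linkage), the dendrogram is cut into ``k``
sub-trees, and clusters are named from arm-level dosage evidence alone:

* ``1p/19q`` — median 1p and 19q arm means at or below ``-tau`` (co-deletion);
* ``7a10d``  — median chromosome-7 arm means at or above ``+tau`` and
  chromosome-10 arm means at or below ``-tau`` (gain of 7, loss of 10);
* ``IDHme``  — no recurrent arm-level lesion.

The IDH-mutation fraction per cluster is reported for characterization but is
not used by the labelling decision.  Outliers are flagged (never deleted):
the union of a user-provided exclusion list and an automatic rule that flags
any sample remaining a singleton when the dendrogram is cut at ``k + 1``.
The threshold ``tau`` defaults to 0.2, midway between the noise level of arm
means (~0) and a single-copy arm loss (~-0.5 in log2).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import GeneAnnotationTable

__all__ = [
    "hierarchical_cluster",
    "exclude_outliers",
    "compute_arm_summary",
    "assign_labels",
    "tabulate_mutations",
    "derive_subgroups",
]

LABEL_CODELETION = "1p/19q"
LABEL_IDHME = "IDHme"
LABEL_7A10D = "7a10d"


def _sample_linkage(cnv: pd.DataFrame) -> np.ndarray:
    # samples are columns; cluster them on their gene profiles
    return linkage(cnv.to_numpy().T, method="complete", metric="euclidean")


def hierarchical_cluster(cnv: pd.DataFrame, k: int) -> pd.Series:
    """Cut the complete-linkage dendrogram of sample columns into k clusters.

    Returns a Series sample -> cluster index in 1..k.  Deterministic for a
    given column order (SciPy breaks merge ties by the smaller index pair).
    """
    n = cnv.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    if k == 1:
        return pd.Series(1, index=cnv.columns, name="cluster")
    Z = _sample_linkage(cnv)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cnv.columns, name="cluster")


def exclude_outliers(
    cnv: pd.DataFrame,
    *,
    k: int = 3,
    exclude_list: Iterable[str] = (),
    automatic: bool = True,
) -> set[str]:
    """Samples to exclude: the user list plus automatic singleton detection.

    The automatic rule flags any sample that remains a singleton cluster when
    the dendrogram is cut into ``k + 1`` sub-trees — a generalization of
    removing the single "obvious outlier" by eye.
    """
    excluded = {s for s in exclude_list if s in cnv.columns}
    if automatic and cnv.shape[1] > k + 1:
        clusters = hierarchical_cluster(cnv, k + 1)
        sizes = clusters.value_counts()
        singletons = set(clusters.index[clusters.isin(sizes.index[sizes == 1])])
        if singletons:
            # a noise cohort cut into k+1 parts often isolates an innocent
            # sample; demand that a flagged singleton also sit far from every
            # other sample relative to the cohort's nearest-neighbour scale
            from scipy.spatial.distance import squareform, pdist

            d = squareform(pdist(cnv.to_numpy().T))
            np.fill_diagonal(d, np.inf)
            nn = d.min(axis=1)
            cutoff = 2.0 * float(np.median(nn))
            pos = {s: i for i, s in enumerate(cnv.columns)}
            excluded |= {s for s in singletons if nn[pos[s]] > cutoff}
    if len(excluded) >= cnv.shape[1]:
        raise ValueError("outlier rule would exclude every sample")
    return excluded


def compute_arm_summary(
    cnv: pd.DataFrame,
    annotation: GeneAnnotationTable,
    *,
    drop_unannotated: bool = False,
) -> pd.DataFrame:
    """Mean log2 ratio per sample per chromosome arm (samples x arms)."""
    missing = cnv.index.difference(annotation.gene_ids)
    if len(missing) > 0:
        if not drop_unannotated:
            raise ValueError(
                f"{len(missing)} matrix genes missing from annotation "
                f"(first: {missing[0]!r}); pass drop_unannotated=True to drop"
            )
        cnv = cnv.drop(index=missing)
    arms = annotation.arm_names.reindex(cnv.index)
    summary = cnv.groupby(arms).mean().T
    summary.index.name = "sample_id"
    summary.columns.name = "arm"
    return summary


def _cluster_label(cluster_arms: pd.DataFrame, tau: float) -> str:
    med = cluster_arms.median(axis=0)

    def m(arm: str) -> float:
        return float(med.get(arm, 0.0))

    if m("1p") <= -tau and m("19q") <= -tau:
        return LABEL_CODELETION
    if m("7p") >= tau and m("7q") >= tau and m("10p") <= -tau and m("10q") <= -tau:
        return LABEL_7A10D
    return LABEL_IDHME


def assign_labels(
    clusters: pd.Series,
    arm_summary: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    *,
    tau: float = 0.2,
    excluded: Iterable[str] = (),
) -> pd.DataFrame:
    """Name each cluster from its arm-median dosage pattern.

    Returns a per-sample DataFrame with columns ``cluster``, ``label`` and
    ``excluded``.  The per-cluster IDH1/2-mutation fraction (if clinical data
    is given) is attached as ``result.attrs["idh_fraction"]`` — reported, not
    used for the decision.
    """
    excluded = set(excluded)
    out = pd.DataFrame(index=clusters.index)
    out["cluster"] = clusters
    out["excluded"] = out.index.isin(excluded)
    labels: dict[int, str] = {}
    seen: dict[str, int] = {}
    for c in sorted(clusters[~out["excluded"]].unique()):
        members = clusters.index[(clusters == c) & ~out["excluded"]]
        lab = _cluster_label(arm_summary.loc[members], tau)
        if lab in seen:
            seen[lab] += 1
            warnings.warn(f"two clusters labelled {lab!r}; suffixing", stacklevel=2)
            lab = f"{lab}-{seen[lab]}"
        else:
            seen[lab] = 1
        labels[c] = lab
    out["label"] = out["cluster"].map(labels)
    out.loc[out["excluded"], "label"] = None
    if clinical is not None and "IDH1/2" in clinical.columns:
        idh = clinical["IDH1/2"].reindex(out.index)
        out.attrs["idh_fraction"] = {
            lab: float(idh[(out["label"] == lab)].mean())
            for lab in out["label"].dropna().unique()
        }
    return out


def tabulate_mutations(
    assignment: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: Iterable[str],
) -> dict[str, pd.DataFrame]:
    """Mutated / wild-type counts per subgroup for each gene.

    Returns gene -> DataFrame with rows ("mutated", "wildtype") and one
    column per subgroup label.  Genes absent from the clinical table are
    skipped with a warning.
    """
    kept = assignment[~assignment["excluded"]]
    labels = sorted(kept["label"].unique())
    tables: dict[str, pd.DataFrame] = {}
    for gene in genes:
        if gene not in clinical.columns:
            warnings.warn(f"mutation gene {gene!r} absent from clinical table", stacklevel=2)
            continue
        status = clinical[gene].reindex(kept.index).astype(bool)
        tab = pd.DataFrame(0, index=["mutated", "wildtype"], columns=labels)
        for lab in labels:
            members = kept.index[kept["label"] == lab]
            n_mut = int(status.loc[members].sum())
            tab.loc["mutated", lab] = n_mut
            tab.loc["wildtype", lab] = len(members) - n_mut
        tables[gene] = tab
    return tables


def derive_subgroups(
    cnv: pd.DataFrame,
    annotation: GeneAnnotationTable,
    clinical: pd.DataFrame | None = None,
    *,
    k: int = 3,
    tau: float = 0.2,
    exclude_list: Iterable[str] = (),
    automatic_outliers: bool = True,
    mutation_genes: Iterable[str] | Mapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full subgrouping stage: outliers -> clustering -> arm evidence -> labels.

    Returns (assignment, arm_summary, mutation_tables).
    """
    excluded = exclude_outliers(
        cnv, k=k, exclude_list=exclude_list, automatic=automatic_outliers
    )
    kept = cnv.drop(columns=list(excluded))
    clusters = hierarchical_cluster(kept, k)
    clusters = clusters.reindex(cnv.columns)  # excluded samples -> NaN cluster
    arm_summary = compute_arm_summary(cnv, annotation)
    assignment = assign_labels(
        clusters.dropna().astype(int), arm_summary, clinical, tau=tau
    )
    # keep excluded samples in the output, flagged
    assignment = assignment.reindex(cnv.columns)
    assignment["excluded"] = assignment.index.isin(excluded) | assignment["excluded"].fillna(
        True
    )
    tables: dict[str, pd.DataFrame] = {}
    if clinical is not None:
        genes = list(mutation_genes) if mutation_genes is not None else [
            c for c in clinical.columns if c not in {"grade", "survival_days", "event"}
        ]
        tables = tabulate_mutations(assignment.dropna(subset=["label"]), clinical, genes)
    return assignment, arm_summary, tables
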