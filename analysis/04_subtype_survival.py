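#!/usr/bin/env python
"""Characterize the subgroups: reference-centroid correlation, survival,
and enrichment of the signature.

The reference centroids here are synthetic stand-ins built from the cohort's
own subgroup mean log-ratios (real reference class signatures are external
gene lists); the demonstration shows the correlation machinery assigning
tumors to their own subgroup's centroid.  Survival is compared pairwise
between subgroups with log-rank tests, and signature genes are tested for
annotation-category/pathway enrichment separately by direction.
"""

import argparse
import pickle
from itertools import combinations
from pathlib import Path

import pandas as pd

from oligogrn import io_formats as io
from oligogrn.characterize import (
    centroid_correlate,
    fisher_enrichment,
    km_estimate,
    logrank_test,
    tumor_log_ratios,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--subgroups", type=Path, default=Path("results/subgroups"))
    ap.add_argument("--signature", type=Path, default=Path("results/signature"))
    ap.add_argument("--out", type=Path, default=Path("results/characterize"))
    args = ap.parse_args()

    clinical = io.read_clinical(args.cohort / "clinical.tsv")
    ann = io.read_annotation(args.cohort / "annotation.tsv")
    assignment = pd.read_csv(args.subgroups / "assignment.tsv", sep="\t", index_col=0)
    with open(args.signature / "normalized.pkl", "rb") as fh:
        norm = pickle.load(fh)
    stats_de = pd.read_csv(args.signature / "de_stats.tsv", sep="\t", index_col=0)

    kept = assignment[~assignment["excluded"]]
    tumors = [s for s in kept.index if s in norm.log_cpm.columns]
    normals = [s for s in norm.log_cpm.columns if s not in assignment.index]
    ratios = tumor_log_ratios(norm.log_cpm[tumors], norm.log_cpm[normals])
    args.out.mkdir(parents=True, exist_ok=True)

    # synthetic stand-in centroids: per-subgroup mean log-ratio profile
    centroids = pd.concat(
        {lab: ratios[[s for s in tumors if kept.loc[s, "label"] == lab]].mean(axis=1)
         for lab in sorted(kept["label"].unique())},
        axis=1,
    ).T
    r, p = centroid_correlate(ratios, centroids)
    r.to_csv(args.out / "centroid_correlations.tsv", sep="\t")
    best = r.idxmax(axis=1)
    agree = (best == kept.loc[best.index, "label"]).mean()
    print(f"centroid classification: {agree:.0%} of tumors correlate highest "
          f"with their own subgroup's centroid")

    # survival
    rows = []
    for la, lb in combinations(sorted(kept["label"].unique()), 2):
        ra = clinical.loc[[s for s in kept.index[kept["label"] == la]]]
        rb = clinical.loc[[s for s in kept.index[kept["label"] == lb]]]
        chi2, pv = logrank_test(ra["survival_days"], ra["event"],
                                rb["survival_days"], rb["event"])
        rows.append({"group_a": la, "group_b": lb, "chi2": chi2, "p": pv})
        print(f"log-rank {la} vs {lb}: chi2={chi2:.2f}, p={pv:.3g}")
    pd.DataFrame(rows).to_csv(args.out / "logrank.tsv", sep="\t", index=False)
    km_rows = []
    for lab in sorted(kept["label"].unique()):
        rec = clinical.loc[[s for s in kept.index[kept["label"] == lab]]]
        km = km_estimate(rec["survival_days"], rec["event"])
        km["label"] = lab
        km_rows.append(km)
    pd.concat(km_rows).to_csv(args.out / "km_curves.tsv", sep="\t")

    # enrichment
    sel = stats_de[stats_de["selected"]]
    by_dir = {"up": set(sel.index[sel["direction"] == "up"]),
              "down": set(sel.index[sel["direction"] == "down"])}
    universe = set(stats_de.index)
    cats: dict[str, set] = {}
    for gene, row in ann.table.iterrows():
        for c in row["categories"]:
            cats.setdefault(f"category:{c}", set()).add(gene)
        for pw in row["pathways"]:
            cats.setdefault(f"pathway:{pw}", set()).add(gene)
    enr = fisher_enrichment(by_dir, cats, universe)
    enr.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    top = enr.nsmallest(3, "p")
    for _, row in top.iterrows():
        print(f"enrichment: {row['category']} ({row['direction']}) "
              f"OR={row['odds_ratio']:.2f} p={row['p']:.3g}")


if __name__ == "__main__":
    main()
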