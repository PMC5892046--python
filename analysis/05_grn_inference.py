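#!/usr/bin/env python
"""Infer the signature-specific regulatory network and analyse its hubs.

Fits, for every signature gene, lasso models screened by the covariance test
(p<5e-5) under two predictor designs — the gene's own copy number alone, and
copy number plus all signature-TF expression — across repeated random
2/3-train / 1/3-test subsamples of the 1p/19q+IDHme tumors.  Links present
in at least 75% of iterations form the consensus network; hub TFs
(out-degree >= 10), modules, and the HOX/SOX family table are reported.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from oligogrn import io_formats as io
from oligogrn.grn import (
    consensus,
    cross_validate,
    family_signature,
    hub_analysis,
    validation_summary,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--subgroups", type=Path, default=Path("results/subgroups"))
    ap.add_argument("--signature", type=Path, default=Path("results/signature"))
    ap.add_argument("--out", type=Path, default=Path("results/grn"))
    ap.add_argument("--iters", type=int, default=50)
    ap.add_argument("--alpha", type=float, default=5e-5)
    ap.add_argument("--freq", type=float, default=0.75)
    ap.add_argument("--min-out", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cnv = io.read_matrix(args.cohort / "cnv.tsv")
    ann = io.read_annotation(args.cohort / "annotation.tsv")
    assignment = pd.read_csv(args.subgroups / "assignment.tsv", sep="\t", index_col=0)
    with open(args.signature / "normalized.pkl", "rb") as fh:
        norm = pickle.load(fh)
    signature = (args.signature / "signature_genes.txt").read_text().split()
    stats_de = pd.read_csv(args.signature / "de_stats.tsv", sep="\t", index_col=0)

    kept = assignment[~assignment["excluded"]]
    samples = [s for s in kept.index[kept["label"].isin(["1p/19q", "IDHme"])]
               if s in norm.log_cpm.columns]
    responses = [g for g in signature if g in cnv.index and g in norm.log_cpm.index]
    tfs = [g for g in responses if g in set(ann.tf_genes())]
    print(f"{len(responses)} signature genes ({len(tfs)} TFs) x {len(samples)} tumors; "
          f"{args.iters} subsampling iterations")

    expr = norm.log_cpm.loc[responses, samples]
    cnv_sub = cnv.loc[responses, samples]
    results = {}
    for mode in ("cnv", "cnv+exp"):
        results[mode] = cross_validate(
            expr, cnv_sub, responses, tfs, mode=mode, n_iter=args.iters,
            alpha=args.alpha, seed=args.seed,
        )
        val = validation_summary(results[mode])
        print(f"  {mode}: median test correlation {val.median_correlation:.3f} "
              f"({val.frac_significant:.0%} genes p<0.05; "
              f"{val.n_never_modeled} never modeled)")

    args.out.mkdir(parents=True, exist_ok=True)
    net = consensus(results["cnv+exp"], args.freq)
    io.write_consensus_network(net.counts, args.out / "consensus_network.tsv")
    pd.DataFrame(
        {"cnv": validation_summary(results["cnv"]).per_gene,
         "cnv+exp": validation_summary(results["cnv+exp"]).per_gene}
    ).to_csv(args.out / "validation_correlations.tsv", sep="\t")

    edges = net.retained_links()
    pd.DataFrame(edges, columns=["source", "target", "sign", "count"]).to_csv(
        args.out / "edges.tsv", sep="\t", index=False)
    hubs, subnet, modules = hub_analysis(net, args.min_out)
    (args.out / "hubs.txt").write_text("\n".join(hubs) + ("\n" if hubs else ""))
    degrees = net.out_degrees().sort_values(ascending=False)
    degrees.to_csv(args.out / "out_degrees.tsv", sep="\t")
    print(f"consensus: {len(edges)} retained links; "
          f"{len(hubs)}/{len(tfs)} hub TFs (out-degree >= {args.min_out}); "
          f"{len(modules)} modules in the hub subnetwork")

    fam = family_signature(net, stats_de["log2_fc"])
    fam.to_csv(args.out / "family_signature.tsv", sep="\t", index=False)
    if not fam.empty:
        for family, grp in fam.groupby("family"):
            dirs = grp["direction"].value_counts().to_dict()
            print(f"  {family} genes in network: {len(grp)} ({dirs})")


if __name__ == "__main__":
    main()
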