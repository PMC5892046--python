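#!/usr/bin/env python
"""Derive the expression signature separating the co-deleted subgroup from
the IDH-mutation-enriched subgroup.

Jointly normalizes tumor and normal-brain counts (log2-CPM, cyclic loess,
precision weights), runs the weighted moderated test between the 1p/19q and
IDHme subgroups, selects the q<0.01 signature, and repeats the contrast
between WHO grades II and III inside each subgroup (restricted to signature
genes).
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from oligogrn import io_formats as io
from oligogrn.de import grade_comparison, moderated_test, normalize, select_signature


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--subgroups", type=Path, default=Path("results/subgroups"))
    ap.add_argument("--out", type=Path, default=Path("results/signature"))
    ap.add_argument("--qcut", type=float, default=0.01)
    args = ap.parse_args()

    counts = io.read_matrix(args.cohort / "counts.tsv")
    clinical = io.read_clinical(args.cohort / "clinical.tsv")
    assignment = pd.read_csv(args.subgroups / "assignment.tsv", sep="\t", index_col=0)

    groups = pd.Series("normal", index=counts.columns, name="group")
    labels = assignment["label"].reindex(counts.columns)
    groups[labels.notna().to_numpy()] = labels.dropna()
    norm = normalize(counts, groups)
    print(f"normalized {norm.log_cpm.shape[0]} genes x {norm.log_cpm.shape[1]} samples "
          f"({norm.n_filtered} low-expression genes filtered)")

    kept = assignment[~assignment["excluded"]]
    a = [s for s in kept.index[kept["label"] == "1p/19q"] if s in norm.log_cpm.columns]
    b = [s for s in kept.index[kept["label"] == "IDHme"] if s in norm.log_cpm.columns]
    res = select_signature(moderated_test(norm, a, b), args.qcut)
    args.out.mkdir(parents=True, exist_ok=True)
    res.to_csv(args.out / "de_stats.tsv", sep="\t")
    signature = list(res.index[res["selected"]])
    (args.out / "signature_genes.txt").write_text("\n".join(signature) + "\n")
    with open(args.out / "normalized.pkl", "wb") as fh:
        pickle.dump(norm, fh)

    print(f"signature: {len(signature)} genes at q<{args.qcut} "
          f"({res.attrs['frac_up']:.0%} up / {res.attrs['frac_down']:.0%} down in 1p/19q vs IDHme)")
    for label in ("1p/19q", "IDHme"):
        try:
            gres = grade_comparison(norm, assignment, clinical, label, signature, q_cut=args.qcut)
            n = int(gres["selected"].sum())
            print(f"grade II vs III within {label}: {n} signature genes at q<{args.qcut}")
        except ValueError as exc:
            print(f"grade II vs III within {label}: skipped ({exc})")


if __name__ == "__main__":
    main()
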