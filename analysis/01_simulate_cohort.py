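#!/usr/bin/env python
"""Generate the study cohort: 193 tumors in three molecular subgroups.

Writes the observed copy-number matrix, RNA-seq counts (tumors + 3 normal
brain references), clinical table, gene annotation and the planted ground
truth under results/cohort/.
"""

import argparse
from pathlib import Path

from oligogrn import io_formats as io
from oligogrn.simulate import CohortConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = CohortConfig(seed=args.seed)
    cohort = generate_cohort(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_matrix(cohort.cnv, args.out / "cnv.tsv")
    io.write_matrix(cohort.counts, args.out / "counts.tsv")
    io.write_clinical(cohort.clinical, args.out / "clinical.tsv")
    io.write_annotation(cohort.annotation, args.out / "annotation.tsv")
    cohort.truth.true_subgroup.to_csv(args.out / "truth_subgroups.tsv", sep="\t")
    with open(args.out / "truth_links.tsv", "w") as fh:
        fh.write("tf\ttarget\tsign\teffect\n")
        for tf, tgt, sign, effect in sorted(cohort.truth.true_links):
            fh.write(f"{tf}\t{tgt}\t{sign}\t{effect:.6g}\n")
    (args.out / "normal_ids.txt").write_text("\n".join(cohort.normal_ids) + "\n")

    sizes = cohort.truth.true_subgroup.value_counts().to_dict()
    print(f"cohort: {cohort.cnv.shape[1]} tumors ({sizes}), "
          f"{cohort.cnv.shape[0]} genes, {len(cohort.truth.true_links)} planted links, "
          f"{len(cohort.truth.true_de_genes)} truly DE genes")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
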