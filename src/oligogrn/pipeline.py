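"""End-to-end pipeline: synthetic or real inputs -> subgroups -> signature ->
characterization -> regulatory network.

Stages run in dependency order, write their outputs as TSV under the run's
output directory, and are cached: each stage writes a manifest with checksums
of its inputs and parameters, and a rerun with an unchanged manifest skips
the stage.  Reports contain no timestamps, so a rerun with the same seed and
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize as ch
from . import de as de_mod
from . import grn as grn_mod
from . import io_formats as io
from . import simulate as sim
from . import subgroups as sg

logger = logging.getLogger("oligogrn")

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "ConfigError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``synth`` is set (a :class:`~oligogrn.simulate.CohortConfig`, the
    pipeline generates its own inputs) or the four input paths must point to
    existing files.
    """

    out_dir: str | Path = "results/run"
    seed: int = 0
    # inputs (ignored when synth is given)
    synth: sim.CohortConfig | None = None
    cnv_path: str | None = None
    counts_path: str | None = None
    clinical_path: str | None = None
    annotation_path: str | None = None
    centroids_path: str | None = None
    normal_ids: list[str] = dataclasses.field(default_factory=list)
    # thresholds
    k: int = 3
    tau: float = 0.2
    q_cut: float = 0.01
    alpha: float = 5e-5
    iters: int = 100
    train_frac: float = 2.0 / 3.0
    freq: float = 0.75
    min_out: int = 10
    exclude_list: list[str] = dataclasses.field(default_factory=list)
    stages: tuple[str, ...] = ("synth", "subgroup", "signature", "characterize", "grn")
    max_steps: int = 20

    def validate(self) -> None:
        if self.iters < 1:
            raise ConfigError("iters must be >= 1")
        if not (0 < self.train_frac < 1):
            raise ConfigError("train_frac must be in (0, 1)")
        if not (0 < self.freq <= 1):
            raise ConfigError("freq must be in (0, 1]")
        if not (0 < self.q_cut < 1) or not (0 < self.alpha < 1):
            raise ConfigError("q_cut and alpha must be in (0, 1)")
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.synth is None:
            for name in ("cnv_path", "counts_path", "clinical_path", "annotation_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"{name} required when no synthetic config is given")


def _checksum(parts: list[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()


def _file_sum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Checksum-based stage cache."""

    def __init__(self, out_dir: Path, name: str):
        self.name = name
        self.manifest = out_dir / f"{name}.manifest.json"

    def fresh(self, key: str, outputs: list[Path]) -> bool:
        if not self.manifest.exists():
            return False
        try:
            recorded = json.loads(self.manifest.read_text())
        except json.JSONDecodeError:
            return False
        return recorded.get("key") == key and all(p.exists() for p in outputs)

    def record(self, key: str) -> None:
        self.manifest.write_text(json.dumps({"stage": self.name, "key": key}, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run report (also written to
    ``report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    try:
        paths = _stage_synth(config, out, report)
        assignment, arm_summary = _stage_subgroup(config, out, paths, report)
        norm, signature, sig_result = _stage_signature(config, out, paths, assignment, report)
        _stage_characterize(config, out, paths, assignment, norm, sig_result, report)
        _stage_grn(config, out, paths, assignment, norm, signature, sig_result, report)
    except (ConfigError,):
        raise
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError(f"stage failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=1, default=str))
    return report


def _stage_synth(config: RunConfig, out: Path, report: dict) -> dict[str, Path]:
    paths = {
        "cnv": out / "synthetic" / "cnv.tsv",
        "counts": out / "synthetic" / "counts.tsv",
        "clinical": out / "synthetic" / "clinical.tsv",
        "annotation": out / "synthetic" / "annotation.tsv",
        "truth": out / "synthetic" / "truth_subgroups.tsv",
        "normals": out / "synthetic" / "normal_ids.txt",
    }
    if config.synth is None or "synth" not in config.stages:
        return {
            "cnv": Path(config.cnv_path),
            "counts": Path(config.counts_path),
            "clinical": Path(config.clinical_path),
            "annotation": Path(config.annotation_path),
        }
    stage = _Stage(out, "synth")
    key = _checksum([json.dumps(dataclasses.asdict(config.synth), sort_keys=True, default=str)])
    if not stage.fresh(key, list(paths.values())):
        logger.info("stage synth: generating cohort")
        (out / "synthetic").mkdir(exist_ok=True)
        cohort = sim.generate_cohort(config.synth)
        io.write_matrix(cohort.cnv, paths["cnv"])
        io.write_matrix(cohort.counts, paths["counts"])
        io.write_clinical(cohort.clinical, paths["clinical"])
        io.write_annotation(cohort.annotation, paths["annotation"])
        cohort.truth.true_subgroup.to_csv(paths["truth"], sep="\t")
        paths["normals"].write_text("\n".join(cohort.normal_ids) + "\n")
        stage.record(key)
    else:
        logger.info("stage synth: cached, skipping")
    report["stages"].append("synth")
    return paths


def _load_inputs(paths: dict[str, Path]):
    cnv = io.read_matrix(paths["cnv"])
    counts = io.read_matrix(paths["counts"])
    clinical = io.read_clinical(paths["clinical"])
    ann = io.read_annotation(paths["annotation"])
    return cnv, counts, clinical, ann


def _stage_subgroup(config, out: Path, paths, report):
    cnv, _, clinical, ann = _load_inputs(paths)
    assignment, arm_summary, tables = sg.derive_subgroups(
        cnv, ann, clinical, k=config.k, tau=config.tau, exclude_list=config.exclude_list
    )
    assignment.to_csv(out / "subgroups.tsv", sep="\t")
    arm_summary.to_csv(out / "arm_summary.tsv", sep="\t")
    with open(out / "mutation_tables.tsv", "w") as fh:
        for gene, tab in tables.items():
            fh.write(f"# {gene}\n")
            tab.to_csv(fh, sep="\t")
    sizes = assignment[~assignment["excluded"]]["label"].value_counts().to_dict()
    report["subgroup_sizes"] = {str(k): int(v) for k, v in sorted(sizes.items())}
    report["n_excluded"] = int(assignment["excluded"].sum())
    report["stages"].append("subgroup")
    logger.info("stage subgroup: %s", report["subgroup_sizes"])
    return assignment, arm_summary


def _stage_signature(config, out: Path, paths, assignment, report):
    _, counts, clinical, _ = _load_inputs(paths)
    normal_ids = [s for s in counts.columns if s not in assignment.index]
    groups = pd.Series("normal", index=counts.columns, name="group")
    tumor_labels = assignment["label"].reindex(counts.columns)
    groups[tumor_labels.notna().to_numpy()] = tumor_labels.dropna()
    norm = de_mod.normalize(counts, groups)

    kept = assignment[~assignment["excluded"]]
    grp_a = [s for s in kept.index[kept["label"] == sg.LABEL_CODELETION] if s in norm.log_cpm.columns]
    grp_b = [s for s in kept.index[kept["label"] == sg.LABEL_IDHME] if s in norm.log_cpm.columns]
    result = de_mod.moderated_test(norm, grp_a, grp_b)
    result = de_mod.select_signature(result, config.q_cut)
    result.to_csv(out / "de_stats.tsv", sep="\t")
    signature = list(result.index[result["selected"]])
    (out / "signature_genes.txt").write_text("\n".join(signature) + "\n")

    report["n_signature"] = len(signature)
    report["frac_up"] = result.attrs.get("frac_up")
    # within-subgroup grade comparison, where both grades are present
    grade_counts = {}
    for label in (sg.LABEL_CODELETION, sg.LABEL_IDHME):
        try:
            gres = de_mod.grade_comparison(
                norm, assignment, clinical, label, signature, q_cut=config.q_cut
            )
            grade_counts[label] = int(gres["selected"].sum())
        except ValueError:
            grade_counts[label] = None
    report["grade_de_counts"] = grade_counts
    report["stages"].append("signature")
    logger.info("stage signature: %d genes at q<%g", len(signature), config.q_cut)
    return norm, signature, result


def _stage_characterize(config, out: Path, paths, assignment, norm, sig_result, report):
    _, counts, clinical, ann = _load_inputs(paths)
    normal_ids = [s for s in norm.log_cpm.columns if s not in assignment.index]
    tumor_ids = [s for s in norm.log_cpm.columns if s in assignment.index]
    ratios = ch.tumor_log_ratios(norm.log_cpm[tumor_ids], norm.log_cpm[normal_ids])

    if config.centroids_path:
        centroids = pd.read_csv(config.centroids_path, sep="\t", index_col=0)
    else:
        # synthetic stand-in reference: centroids sampled from subgroup means
        centroids = None
    if centroids is not None:
        r, p = ch.centroid_correlate(ratios, centroids)
        r.to_csv(out / "centroid_correlations.tsv", sep="\t")
        p.to_csv(out / "centroid_correlation_p.tsv", sep="\t")

    # survival: KM per subgroup + pairwise log-rank
    kept = assignment[~assignment["excluded"]]
    km_rows, lr_rows = [], []
    for label in sorted(kept["label"].dropna().unique()):
        ids = [s for s in kept.index[kept["label"] == label] if s in clinical.index]
        rec = clinical.loc[ids]
        if rec.empty:
            continue
        km = ch.km_estimate(rec["survival_days"], rec["event"])
        km["label"] = label
        km_rows.append(km)
    if km_rows:
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t")
    labels = sorted(kept["label"].dropna().unique())
    for la, lb in combinations(labels, 2):
        ra = clinical.loc[[s for s in kept.index[kept["label"] == la] if s in clinical.index]]
        rb = clinical.loc[[s for s in kept.index[kept["label"] == lb] if s in clinical.index]]
        chi2, p = ch.logrank_test(
            ra["survival_days"], ra["event"], rb["survival_days"], rb["event"]
        )
        lr_rows.append({"group_a": la, "group_b": lb, "chi2": chi2, "p": p})
    pd.DataFrame(lr_rows).to_csv(out / "logrank.tsv", sep="\t", index=False)
    report["logrank"] = {f"{r['group_a']} vs {r['group_b']}": r["p"] for r in lr_rows}

    # enrichment of the signature against annotation categories and pathways
    sel = sig_result[sig_result["selected"]]
    by_dir = {
        "up": set(sel.index[sel["direction"] == "up"]),
        "down": set(sel.index[sel["direction"] == "down"]),
    }
    universe = set(sig_result.index)
    cats: dict[str, set[str]] = {}
    for gene, row in ann.table.iterrows():
        for c in row["categories"]:
            cats.setdefault(f"category:{c}", set()).add(gene)
        for pw in row["pathways"]:
            cats.setdefault(f"pathway:{pw}", set()).add(gene)
    enr = ch.fisher_enrichment(by_dir, cats, universe)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report["stages"].append("characterize")


def _stage_grn(config, out: Path, paths, assignment, norm, signature, sig_result, report):
    cnv, _, _, ann = _load_inputs(paths)
    kept = assignment[~assignment["excluded"]]
    samples = [
        s
        for s in kept.index[kept["label"].isin([sg.LABEL_CODELETION, sg.LABEL_IDHME])]
        if s in norm.log_cpm.columns
    ]
    responses = [g for g in signature if g in cnv.index]
    tf_all = set(ann.tf_genes())
    tfs = [g for g in responses if g in tf_all]
    expr = norm.log_cpm.loc[responses, samples]
    cnv_sub = cnv.loc[responses, samples]

    results = {}
    for mode in ("cnv", "cnv+exp"):
        results[mode] = grn_mod.cross_validate(
            expr,
            cnv_sub,
            responses,
            tfs,
            mode=mode,
            n_iter=config.iters,
            train_frac=config.train_frac,
            alpha=config.alpha,
            max_steps=config.max_steps,
            seed=config.seed,
        )
    net = grn_mod.consensus(results["cnv+exp"], config.freq)
    io.write_consensus_network(net.counts, out / "consensus_network.tsv")

    val = {mode: grn_mod.validation_summary(res) for mode, res in results.items()}
    pd.DataFrame(
        {
            "cnv": val["cnv"].per_gene,
            "cnv+exp": val["cnv+exp"].per_gene,
        }
    ).to_csv(out / "validation_correlations.tsv", sep="\t")
    report["median_validation"] = {
        mode: (None if np.isnan(v.median_correlation) else round(v.median_correlation, 4))
        for mode, v in val.items()
    }
    report["n_never_modeled"] = {mode: v.n_never_modeled for mode, v in val.items()}

    hubs, subnet, modules = grn_mod.hub_analysis(net, config.min_out)
    (out / "hubs.txt").write_text("\n".join(hubs) + ("\n" if hubs else ""))
    with open(out / "modules.tsv", "w") as fh:
        fh.write("module\tgene\n")
        for i, mod in enumerate(modules):
            for gene in sorted(mod):
                fh.write(f"{i}\t{gene}\n")
    edges = net.retained_links()
    pd.DataFrame(edges, columns=["source", "target", "sign", "count"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    fam = grn_mod.family_signature(net, sig_result["log2_fc"])
    fam.to_csv(out / "family_signature.tsv", sep="\t", index=False)
    report["n_hubs"] = len(hubs)
    report["n_retained_links"] = len(edges)
    report["n_modules"] = len(modules)
    report["family_table_rows"] = len(fam)
    report["stages"].append("grn")
    logger.info(
        "stage grn: %d links retained, %d hubs, median r %s",
        len(edges),
        len(hubs),
        report["median_validation"],
    )
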