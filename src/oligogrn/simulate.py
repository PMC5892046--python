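"""Synthetic oligodendroglioma-like cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: three molecular subgroups with arm-level copy-number archetypes
(1p/19q co-deletion; chromosome-7 gain plus chromosome-10 loss; no recurrent
lesion), subgroup-specific mutation frequencies, RNA-seq counts whose
log-scale means combine copy-number dosage, planted subgroup expression
offsets and a sparse signed TF regulatory network, negative-binomial counting
noise with log-normal library sizes, normal-brain reference samples, WHO
grade labels, and exponential survival with subgroup-specific hazards.

Copy number is modelled in two layers: a *biological dosage* component
(arm archetype plus per-gene dosage variation) that feeds expression, and an
additional measurement-noise component that only appears in the observed
copy-number matrix.  Only the dosage layer is predictive of expression, which
reproduces the regime in real tumor data where copy-number-only expression
models explain modest variance while TF-expression models explain much more.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotationTable, MUTATION_GENES

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_reference_signatures",
    "draw_tumor_from_centroid",
    "simulate_de_counts",
]


class ConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


#: approximate chromosome-arm lengths in Mb (p, q), autosomes only; genes are
#: placed on arms with probability proportional to these lengths
ARM_LENGTHS_MB: dict[str, tuple[float, float]] = {
    "1": (123, 125), "2": (93, 149), "3": (91, 107), "4": (50, 140),
    "5": (48, 133), "6": (60, 111), "7": (60, 99), "8": (45, 101),
    "9": (49, 92), "10": (40, 94), "11": (53, 82), "12": (36, 98),
    "13": (18, 96), "14": (17, 90), "15": (19, 83), "16": (36, 54),
    "17": (25, 58), "18": (17, 61), "19": (26, 33), "20": (28, 36),
    "21": (13, 34), "22": (15, 36),
}

#: per-subgroup mutation frequencies of the six recurrently mutated genes,
#: matching the tabulated counts of the study cohort (133/45/15 tumors)
DEFAULT_MUTATION_FREQS: dict[str, dict[str, float]] = {
    "1p/19q": {
        "IDH1/2": 133 / 133, "TP53": 7 / 133, "ATRX": 3 / 133,
        "CIC": 85 / 133, "FUBP1": 38 / 133, "NOTCH1": 31 / 133,
    },
    "IDHme": {
        "IDH1/2": 37 / 45, "TP53": 35 / 45, "ATRX": 30 / 45,
        "CIC": 2 / 45, "FUBP1": 0 / 45, "NOTCH1": 3 / 45,
    },
    "7a10d": {
        "IDH1/2": 3 / 15, "TP53": 6 / 15, "ATRX": 3 / 15,
        "CIC": 0 / 15, "FUBP1": 0 / 15, "NOTCH1": 0 / 15,
    },
}

DEFAULT_ARM_EFFECTS: dict[str, dict[str, float]] = {
    "1p/19q": {"1p": -0.5, "19q": -0.5},
    "IDHme": {},
    "7a10d": {"7p": +0.5, "7q": +0.5, "10p": -0.5, "10q": -0.5},
}

GENE_CATEGORIES = (
    "kinase",
    "phosphatase",
    "tumor suppressor",
    "signaling pathway gene",
)

PATHWAYS = (
    "MAPK signaling",
    "PI3K-Akt signaling",
    "Wnt signaling",
    "Apoptosis",
    "Pentose phosphate",
    "Pyrimidine metabolism",
)


@dataclasses.dataclass
class CohortConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the study conditions: 133/45/15 tumors per subgroup,
    arm-level log2 shifts of +-0.5, mutation frequencies from the cohort's
    mutation table, and three normal-brain references.
    """

    n_per_subgroup: tuple[int, int, int] = (133, 45, 15)
    subgroup_labels: tuple[str, str, str] = ("1p/19q", "IDHme", "7a10d")
    n_genes: int = 6000
    n_tfs: int = 150
    arm_effects: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARM_EFFECTS.items()}
    )
    mutation_freqs: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MUTATION_FREQS.items()}
    )
    # copy number: total observed per-gene noise SD, and the biological
    # (dosage) share of it that propagates into expression
    cnv_noise_sd: float = 0.3
    cnv_bio_sd: float = 0.15
    cnv_dosage_slope: float = 1.0
    # regulatory network over TF -> gene pairs
    network_density: float = 0.01
    link_effect_sd: float = 0.5
    link_effect_floor: float = 0.4
    tf_noise_sd: float = 0.6
    gene_noise_sd: float = 0.15
    # planted subgroup expression programs: a fraction of TFs carries a
    # subgroup-1-vs-2 offset, which propagates to targets through the
    # network; non-TF genes acquire expression differences only via their
    # regulators and copy-number dosage
    de_frac: float = 0.3
    de_lfc: float = 1.0
    de_call_threshold: float = 0.5  # |group mean diff| calling a gene truly DE
    # rename eight offset-carrying TFs to HOX/SOX symbols with coherent
    # directions (HOX down, SOX up in subgroup 1 vs 2)
    plant_families: bool = True
    # optional within-subgroup grade effect
    grade3_frac: tuple[float, float, float] = (0.45, 0.27, 0.5)
    grade_de_genes: int = 0
    grade_de_lfc: float = 0.5
    grade_de_subgroup: int = 0
    # counting model
    nb_dispersion: float = 0.01
    baseline_log2_range: tuple[float, float] = (5.0, 10.0)
    library_sigma: float = 0.3
    n_normals: int = 3
    # survival (rates per day)
    survival_hazards: tuple[float, float, float] = (1 / 3000, 1 / 3000, 1 / 500)
    censoring_rate: float = 0.3
    # planted outliers: samples whose copy-number column is pure noise at
    # `outlier_scale` times the nominal noise SD
    n_outliers: int = 0
    outlier_scale: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_subgroup) != 3 or any(n < 0 for n in self.n_per_subgroup):
            raise ConfigError("n_per_subgroup must be three nonnegative integers")
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs must not exceed n_genes")
        if not (0.0 <= self.network_density <= 1.0):
            raise ConfigError("network_density must be in [0, 1]")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError("censoring_rate must be in [0, 1)")
        if any(h <= 0 for h in self.survival_hazards):
            raise ConfigError("survival hazards must be positive")
        if self.cnv_bio_sd > self.cnv_noise_sd:
            raise ConfigError("cnv_bio_sd cannot exceed cnv_noise_sd")
        for grp, freqs in self.mutation_freqs.items():
            for gene, f in freqs.items():
                if not (0.0 <= f <= 1.0):
                    raise ConfigError(f"mutation freq {grp}/{gene} outside [0,1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    true_subgroup: pd.Series  # sample -> label
    true_links: set[tuple[str, str, int, float]]  # (tf, target, sign, effect)
    true_de_genes: set[tuple[str, str]]  # (gene, "up"/"down") in subgroup1 vs 2
    planted_outliers: set[str]
    true_grade_de_genes: set[str] = dataclasses.field(default_factory=set)
    #: exact expected log2 group-mean difference (subgroup1 - subgroup2) per
    #: gene, from the generative model (offsets + dosage + propagated links)
    true_group_diff: pd.Series | None = None


@dataclasses.dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    cnv: pd.DataFrame  # genes x tumors, observed log2 ratios
    counts: pd.DataFrame | None  # genes x (tumors + normals) raw counts
    clinical: pd.DataFrame  # indexed by tumor sample id
    annotation: GeneAnnotationTable
    truth: SyntheticTruth
    normal_ids: list[str]

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.cnv.columns)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _make_annotation(rng: np.random.Generator, cfg: CohortConfig) -> GeneAnnotationTable:
    arms = [(c, a) for c in ARM_LENGTHS_MB for a in ("p", "q")]
    lengths = np.array([ARM_LENGTHS_MB[c][0 if a == "p" else 1] for c, a in arms], float)
    probs = lengths / lengths.sum()
    arm_idx = rng.choice(len(arms), size=cfg.n_genes, p=probs)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    tf_idx = rng.choice(cfg.n_genes, size=cfg.n_tfs, replace=False)
    is_tf = np.zeros(cfg.n_genes, bool)
    is_tf[tf_idx] = True
    starts = rng.integers(1, 100_000_000, size=cfg.n_genes)
    cats, paths = [], []
    for i in range(cfg.n_genes):
        c = {cat for cat in GENE_CATEGORIES if rng.random() < 0.05}
        if is_tf[i]:
            c.add("transcription factor/cofactor")
        cats.append(frozenset(c))
        paths.append(frozenset(p for p in PATHWAYS if rng.random() < 0.03))
    table = pd.DataFrame(
        {
            "chromosome": [arms[j][0] for j in arm_idx],
            "arm": [arms[j][1] for j in arm_idx],
            "start": starts,
            "end": starts + rng.integers(1_000, 100_000, size=cfg.n_genes),
            "is_tf": is_tf,
            "categories": cats,
            "pathways": paths,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneAnnotationTable(table)


def generate_cohort(config: CohortConfig, *, with_expression: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    With ``with_expression=False`` only copy number, clinical data and
    annotation are produced (cheaper when only the subgrouping stage is
    exercised).  Identical configs yield byte-identical outputs.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    ann = _make_annotation(rng, cfg)
    genes = list(ann.gene_ids)
    arm_names = ann.arm_names.to_numpy()
    n_genes = cfg.n_genes

    n_tumors = sum(cfg.n_per_subgroup)
    tumor_ids = [f"T{i:03d}" for i in range(n_tumors)]
    subgroup = np.repeat(np.arange(3), cfg.n_per_subgroup)
    labels = pd.Series(
        [cfg.subgroup_labels[k] for k in subgroup], index=tumor_ids, name="true_subgroup"
    )

    # --- copy number: archetype + biological dosage noise + measurement noise
    archetype = np.zeros((n_genes, n_tumors))
    for k, lab in enumerate(cfg.subgroup_labels):
        cols = subgroup == k
        for arm, shift in cfg.arm_effects.get(lab, {}).items():
            archetype[np.ix_(arm_names == arm, cols)] = shift
    dosage = archetype + rng.normal(0.0, cfg.cnv_bio_sd, size=(n_genes, n_tumors))
    meas_sd = float(np.sqrt(max(cfg.cnv_noise_sd**2 - cfg.cnv_bio_sd**2, 0.0)))
    observed_cnv = dosage + rng.normal(0.0, meas_sd, size=(n_genes, n_tumors))

    outliers: set[str] = set()
    if cfg.n_outliers > 0:
        out_idx = rng.choice(n_tumors, size=cfg.n_outliers, replace=False)
        for j in out_idx:
            observed_cnv[:, j] = rng.normal(
                0.0, cfg.outlier_scale * cfg.cnv_noise_sd, size=n_genes
            )
            dosage[:, j] = 0.0
            outliers.add(tumor_ids[j])

    cnv = pd.DataFrame(observed_cnv, index=genes, columns=tumor_ids)
    cnv.index.name = "gene_id"

    # --- clinical: mutations, grade, survival
    clinical = pd.DataFrame(index=pd.Index(tumor_ids, name="sample_id"))
    grade3 = np.array([rng.random() < cfg.grade3_frac[k] for k in subgroup])
    clinical["grade"] = np.where(grade3, "III", "II")
    for gene in MUTATION_GENES:
        freqs = np.array(
            [cfg.mutation_freqs[cfg.subgroup_labels[k]].get(gene, 0.0) for k in subgroup]
        )
        clinical[gene] = rng.random(n_tumors) < freqs
    hazards = np.array([cfg.survival_hazards[k] for k in subgroup])
    death = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        c_rate = hazards * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor = rng.exponential(1.0 / c_rate)
    else:
        censor = np.full(n_tumors, np.inf)
    clinical["survival_days"] = np.rint(np.minimum(death, censor)).astype(int)
    clinical["event"] = death <= censor

    # --- planted subgroup expression programs: offsets on a fraction of TFs
    tf_mask = ann.table["is_tf"].to_numpy()
    tf_idx = np.flatnonzero(tf_mask)
    tf_offset = np.zeros(n_genes)
    pick = np.array([], dtype=int)
    if len(tf_idx) > 0 and cfg.de_frac > 0:
        n_de_tf = int(round(cfg.de_frac * len(tf_idx)))
        pick = rng.choice(tf_idx, size=n_de_tf, replace=False)
        signs = np.where(np.arange(n_de_tf) % 2 == 0, 1.0, -1.0)
        tf_offset[pick] = signs * cfg.de_lfc
    if cfg.plant_families and len(pick) >= 8:
        hox = ("HOXA4", "HOXA5", "HOXA7", "HOXC4")
        sox = ("SOX6", "SOX8", "SOX12", "SOX13")
        for j, name in enumerate(hox + sox):
            g = int(pick[j])
            genes[g] = name
            tf_offset[g] = -cfg.de_lfc if name.startswith("HOX") else cfg.de_lfc
        ann.table.index = pd.Index(genes, name="gene_id")
        cnv.index = pd.Index(genes, name="gene_id")

    # --- regulatory network: TF -> target links with signed effects.
    # TF-to-TF links are restricted to a DAG (by TF rank) so regulatory
    # cascades propagate unambiguously to the observed expression.
    tf_rank = {int(t): i for i, t in enumerate(tf_idx)}
    links: set[tuple[str, str, int, float]] = set()
    link_rows: list[tuple[int, int, float]] = []
    if cfg.network_density > 0 and len(tf_idx) > 0:
        present = rng.random((len(tf_idx), n_genes)) < cfg.network_density
        for ti, gi in zip(*np.nonzero(present)):
            tgt = int(gi)
            src = int(tf_idx[ti])
            if src == tgt:  # no self-loops
                continue
            if tgt in tf_rank and tf_rank[tgt] <= tf_rank[src]:
                continue  # keep the TF-TF subgraph acyclic
            sign = 1 if rng.random() < 0.5 else -1
            effect = sign * (cfg.link_effect_floor + abs(rng.normal(0.0, cfg.link_effect_sd)))
            links.add((genes[src], genes[tgt], sign, float(effect)))
            link_rows.append((src, tgt, float(effect)))

    # exact expected subgroup-1-vs-2 log2 difference per gene: own offset
    # plus dosage difference plus propagated parent differences
    arch_diff = np.zeros(n_genes)
    for arm, shift in cfg.arm_effects.get(cfg.subgroup_labels[0], {}).items():
        arch_diff[arm_names == arm] += cfg.cnv_dosage_slope * shift
    for arm, shift in cfg.arm_effects.get(cfg.subgroup_labels[1], {}).items():
        arch_diff[arm_names == arm] -= cfg.cnv_dosage_slope * shift
    # propagate in topological order (links sorted by source TF rank) so a
    # cascade's contribution is fully accumulated before it fans out
    link_rows.sort(key=lambda r: tf_rank[r[0]])
    group_diff = (tf_offset + arch_diff).copy()
    for src, tgt, effect in link_rows:
        group_diff[tgt] += effect * group_diff[src]
    true_de = {
        (genes[g], "up" if group_diff[g] > 0 else "down")
        for g in np.flatnonzero(np.abs(group_diff) >= cfg.de_call_threshold)
    }

    # grade effect: planted on realized-DE genes so it falls inside the
    # signature universe the grade comparison is restricted to
    grade_de_genes: set[str] = set()
    grade_offset = np.zeros(n_genes)
    if cfg.grade_de_genes > 0:
        de_pool = np.flatnonzero(np.abs(group_diff) >= cfg.de_call_threshold)
        if len(de_pool) > 0:
            pick = rng.choice(de_pool, size=min(cfg.grade_de_genes, len(de_pool)), replace=False)
            grade_offset[pick] = cfg.grade_de_lfc * rng.choice([-1.0, 1.0], size=len(pick))
            grade_de_genes = {genes[g] for g in pick}

    truth = SyntheticTruth(
        true_subgroup=labels,
        true_links=links,
        true_de_genes=true_de,
        planted_outliers=outliers,
        true_grade_de_genes=grade_de_genes,
        true_group_diff=pd.Series(group_diff, index=genes, name="group_diff"),
    )

    normal_ids = [f"N{i:02d}" for i in range(cfg.n_normals)]
    if not with_expression:
        return SyntheticCohort(cnv, None, clinical, ann, truth, normal_ids)

    # --- latent log2 expression
    lo, hi = cfg.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    z = baseline[:, None] + cfg.cnv_dosage_slope * dosage
    z[:, subgroup == 0] += tf_offset[:, None]
    intrinsic_sd = np.where(tf_mask, cfg.tf_noise_sd, cfg.gene_noise_sd)
    z += rng.normal(0.0, 1.0, size=(n_genes, n_tumors)) * intrinsic_sd[:, None]
    # network effects: each target responds to the centered *final* signal of
    # its regulator; the topological link order makes cascades consistent
    for src, tgt, effect in link_rows:
        z[tgt] += effect * (z[src] - z[src].mean())
    if cfg.grade_de_genes > 0:
        affected = (subgroup == cfg.grade_de_subgroup) & grade3
        z[:, affected] += grade_offset[:, None]

    z_norm = baseline[:, None] + rng.normal(
        0.0, cfg.gene_noise_sd, size=(n_genes, cfg.n_normals)
    )
    z_all = np.concatenate([z, z_norm], axis=1)
    lib = np.exp(rng.normal(0.0, cfg.library_sigma, size=n_tumors + cfg.n_normals))
    mu = np.exp2(z_all) * lib[None, :]
    counts = pd.DataFrame(
        _nb_counts(rng, mu, cfg.nb_dispersion),
        index=genes,
        columns=tumor_ids + normal_ids,
    )
    counts.index.name = "gene_id"
    return SyntheticCohort(cnv, counts, clinical, ann, truth, normal_ids)


# ---------------------------------------------------------------------------
# reference centroid signatures


def generate_reference_signatures(
    n_classes: int = 4,
    n_genes: int = 100,
    *,
    class_names: Sequence[str] | None = None,
    scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-class centroid log-ratio signatures.

    Returns a classes x genes DataFrame.  Centroids are independent Gaussian
    profiles, so a tumor drawn near centroid k correlates highest with k.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    if class_names is None:
        class_names = [f"class{i+1}" for i in range(n_classes)]
    genes = [f"R{i:04d}" for i in range(n_genes)]
    values = rng.normal(0.0, scale, size=(n_classes, n_genes))
    return pd.DataFrame(values, index=list(class_names), columns=genes)


def draw_tumor_from_centroid(
    centroids: pd.DataFrame, class_name: str, *, snr: float = 2.0, rng=None
) -> pd.Series:
    """Draw a tumor log-ratio profile: centroid plus Gaussian noise at the
    given signal-to-noise ratio (centroid SD over noise SD)."""
    rng = np.random.default_rng(rng)
    mu = centroids.loc[class_name]
    noise_sd = float(mu.std(ddof=0)) / snr if snr > 0 else 0.0
    return mu + rng.normal(0.0, noise_sd, size=len(mu))


# ---------------------------------------------------------------------------
# focused two-group DE simulator (for calibration/power studies)


def simulate_de_counts(
    n_genes: int = 2000,
    n_a: int = 60,
    n_b: int = 40,
    *,
    frac_de: float = 0.1,
    lfc: float = 1.0,
    dispersion: float = 0.2,
    baseline_log2_range: tuple[float, float] = (4.0, 9.0),
    library_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, set[tuple[str, str]]]:
    """Two-group negative-binomial counts with a planted DE fraction.

    Returns (counts genes x samples, group labels per sample, planted DE set
    of (gene, direction) with direction of group A relative to group B).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="group")
    baseline = rng.uniform(*baseline_log2_range, size=n_genes)
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    offset = np.zeros(n_genes)
    offset[de_idx] = sign * lfc
    z = np.tile(baseline[:, None], (1, n_a + n_b))
    z[:, :n_a] += offset[:, None]
    lib = np.exp(rng.normal(0.0, library_sigma, size=n_a + n_b))
    mu = np.exp2(z) * lib[None, :]
    counts = pd.DataFrame(_nb_counts(rng, mu, dispersion), index=genes, columns=samples)
    truth = {(genes[g], "up" if s > 0 else "down") for g, s in zip(de_idx, sign)}
    return counts, groups, truth
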