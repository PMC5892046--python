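"""Readers and writers for the pipeline's tabular artifacts.

All on-disk formats are plain delimited text (TSV by default, CSV accepted):

* gene x sample matrices (copy-number log2 ratios, RNA-seq counts, normalized
  expression) with a header row of sample ids and a first column of gene ids;
* a BED-like gene annotation table (chrom, start, end, gene, arm, TF flag,
  category and pathway memberships);
* a clinical table (sample id, histological grade, per-gene mutation flags,
  survival days, death event);
* the consensus regulatory network matrix (responses x predictors, signed
  integer presence counts).

Coordinates in the annotation are 1-based inclusive.  Gene identity is by
symbol string throughout; no aliasing.  Matrices must be complete — missing
values are rejected unless explicitly dropped with :func:`drop_incomplete`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneAnnotationTable",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "read_consensus_network",
    "write_consensus_network",
    "drop_incomplete",
]

#: columns every clinical table must provide
CLINICAL_REQUIRED = ("sample_id", "grade", "survival_days", "event")

#: mutation genes tabulated in the study cohort
MUTATION_GENES = ("IDH1/2", "TP53", "ATRX", "CIC", "FUBP1", "NOTCH1")

VALID_CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclasses.dataclass
class GeneAnnotationTable:
    """Per-gene genomic annotation.

    Parameters
    ----------
    table
        DataFrame indexed by unique gene symbol with columns ``chromosome``
        (``"1"``..``"22"``, ``"X"``, ``"Y"``), ``arm`` (``"p"``/``"q"``),
        ``start``/``end`` (1-based inclusive), ``is_tf`` (bool),
        ``categories`` and ``pathways`` (frozensets of strings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in annotation: {dup!r}")
        bad_chrom = set(t["chromosome"].astype(str)) - set(VALID_CHROMOSOMES)
        if bad_chrom:
            raise FormatError(f"unknown chromosome(s): {sorted(bad_chrom)}")
        if not t["arm"].isin(["p", "q"]).all():
            raise FormatError("arm must be 'p' or 'q' for every gene")
        if (t["start"] > t["end"]).any():
            g = t.index[t["start"] > t["end"]][0]
            raise FormatError(f"start > end for gene {g!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def arm_names(self) -> pd.Series:
        """Chromosome-arm name per gene, e.g. ``"1p"`` or ``"19q"``."""
        return self.table["chromosome"].astype(str) + self.table["arm"]

    def tf_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"]])


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma when sep is None."""
    path = Path(path)
    if sep is None:
        with open(path, "r", newline="") as fh:
            first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    # engine="c" handles CRLF transparently
    return pd.read_csv(path, sep=sep, header=0, dtype=str)


def read_matrix(
    path: str | Path,
    *,
    sep: str | None = None,
    orientation: str = "genes_by_samples",
) -> pd.DataFrame:
    """Read a gene x sample numeric matrix.

    The first column holds gene ids, the header row sample ids.  With
    ``orientation="samples_by_genes"`` the file is transposed after reading so
    the returned frame is always genes x samples.

    Raises
    ------
    FormatError
        On a missing/blank header, duplicate gene ids, non-numeric cells
        (reported with row and column), or missing values.
    """
    raw = _read_table(path, sep)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected id column plus >=1 data column")
    first_col = raw.columns[0]
    raw = raw.set_index(first_col)
    raw.index = raw.index.astype(str)
    raw.index.name = "gene_id"
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at row {values.index[r]!r}, "
            f"column {values.columns[c]!r}"
        )
    values = values.astype(float)
    if orientation == "samples_by_genes":
        values = values.T
        values.index.name = "gene_id"
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError(f"{path}: non-finite value in matrix")
    return values


def write_matrix(matrix: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    """Write a genes x samples matrix with full float precision."""
    out = matrix.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep=sep, float_format="%.10g")


def drop_incomplete(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop gene rows containing missing values; return (matrix, n_dropped)."""
    keep = matrix.notna().all(axis=1)
    return matrix.loc[keep], int((~keep).sum())


# ---------------------------------------------------------------------------
# annotation


def _join_set(s: Iterable[str]) -> str:
    return ";".join(sorted(s))


def _split_set(s: object) -> frozenset[str]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "" or pd.isna(s):
        return frozenset()
    return frozenset(str(s).split(";"))


def read_annotation(path: str | Path, *, sep: str | None = None) -> GeneAnnotationTable:
    """Read a BED-like annotation: chrom, start, end, gene, arm, is_tf, categories, pathways."""
    raw = _read_table(path, sep)
    required = {"chrom", "start", "end", "gene", "arm"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    n = len(raw)
    is_tf = raw["is_tf"] if "is_tf" in raw else pd.Series(["0"] * n)
    cats = raw["categories"] if "categories" in raw else pd.Series([""] * n)
    paths = raw["pathways"] if "pathways" in raw else pd.Series([""] * n)
    t = pd.DataFrame(
        {
            "chromosome": raw["chrom"].astype(str).to_numpy(),
            "arm": raw["arm"].astype(str).to_numpy(),
            "start": pd.to_numeric(raw["start"]).astype(int).to_numpy(),
            "end": pd.to_numeric(raw["end"]).astype(int).to_numpy(),
            "is_tf": [str(v).strip().lower() in {"1", "true", "yes"} for v in is_tf],
            "categories": [_split_set(v) for v in cats],
            "pathways": [_split_set(v) for v in paths],
        },
        index=pd.Index(raw["gene"].astype(str).to_numpy(), name="gene_id"),
    )
    return GeneAnnotationTable(t)


def write_annotation(ann: GeneAnnotationTable, path: str | Path, *, sep: str = "\t") -> None:
    t = ann.table
    out = pd.DataFrame(
        {
            "chrom": t["chromosome"],
            "start": t["start"],
            "end": t["end"],
            "gene": t.index,
            "arm": t["arm"],
            "is_tf": t["is_tf"].astype(int),
            "categories": t["categories"].map(_join_set),
            "pathways": t["pathways"].map(_join_set),
        }
    )
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# clinical


def read_clinical(
    path: str | Path,
    *,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read the clinical table.

    Returns a DataFrame indexed by ``sample_id`` with columns ``grade``
    (``"II"``/``"III"``), ``survival_days`` (int), ``event`` (bool) and one
    boolean column per mutation gene.  ``column_map`` renames file columns to
    the required schema (the supplementary tables of different cohorts differ
    in their headers).  Unknown extra columns are preserved.
    """
    raw = _read_table(path, sep)
    if raw.empty:
        raise FormatError(f"{path}: clinical table has no rows")
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = set(CLINICAL_REQUIRED) - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    raw = raw.set_index("sample_id")
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    out = pd.DataFrame(index=raw.index)
    grade = raw["grade"].astype(str)
    if not grade.isin(["II", "III"]).all():
        bad = grade[~grade.isin(["II", "III"])].iloc[0]
        raise FormatError(f"{path}: grade must be II or III, got {bad!r}")
    out["grade"] = grade
    days = pd.to_numeric(raw["survival_days"])
    if (days < 0).any():
        raise FormatError(f"{path}: negative survival_days")
    out["survival_days"] = days.astype(int)
    out["event"] = pd.to_numeric(raw["event"]).astype(bool)
    for col in raw.columns:
        if col in {"grade", "survival_days", "event"}:
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.notna().all() and vals.isin([0, 1]).all():
            out[col] = vals.astype(bool)
        else:
            out[col] = raw[col]
    return out


def write_clinical(clinical: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    out = clinical.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# consensus network file (responses x predictors, signed integer counts)


def write_consensus_network(counts: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    """Write the consensus-network count matrix.

    Rows are response (signature) genes, columns predictors (signature TFs
    plus the gene-specific copy-number column).  Cell values are signed
    presence counts: the magnitude is the number of subsampling iterations in
    which the link was selected, the sign the majority coefficient sign
    (positive = activating, negative = repressing).
    """
    out = counts.astype(int).copy()
    out.index.name = "response"
    out.to_csv(path, sep=sep)


def read_consensus_network(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    raw = _read_table(path, sep)
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    raw.index.name = "response"
    counts = raw.apply(pd.to_numeric).astype(int)
    return counts
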