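"""Tabular I/O and cohort containers.

Every on-disk format is plain TSV (tab separated, no quoting, UTF-8);
gene-set collections use the Broad GMT dialect.  Writers prepend a single
``#relapse-delta v<version>`` comment line which readers skip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SCALES = ("counts", "log2rpkm", "cpm")
VALID_TIMEPOINTS = ("primary", "relapse")

_HEADER_COMMENT = "#relapse-delta v"


class MatrixIOError(ValueError):
    """Raised on malformed or inconsistent tabular input."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale
        One of ``counts`` (non-negative integers), ``log2rpkm`` or ``cpm``.
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise MatrixIOError(
                f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise MatrixIOError(f"duplicate gene ids: {dupes[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise MatrixIOError(f"duplicate sample ids: {dupes[:5]}")
        if self.scale == "counts":
            vals = self.values.to_numpy()
            if (vals < 0).any():
                raise MatrixIOError("counts matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise MatrixIOError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], scale=self.scale)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise MatrixIOError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], scale=self.scale)


#: columns required in a cohort annotation table
ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "timepoint",
    "group",
    "subgroup",
    "age_years",
    "sex",
    "relapse_pattern",
    "m_stage",
    "novel_cnv",
    "pfs_months",
    "os_months",
    "os_event",
    "pfs_event",
]


@dataclass
class CohortAnnotation:
    """Per-sample clinical/molecular metadata with patient pairing."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise MatrixIOError(f"annotation missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise MatrixIOError("duplicate sample ids in annotation")
        bad_tp = set(self.table["timepoint"]) - set(VALID_TIMEPOINTS)
        if bad_tp:
            raise MatrixIOError(
                f"unknown timepoint labels {sorted(bad_tp)}; expected {VALID_TIMEPOINTS}"
            )
        for col in ("pfs_months", "os_months"):
            vals = pd.to_numeric(self.table[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise MatrixIOError(f"negative survival time in column {col}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, mask: pd.Series | np.ndarray) -> "CohortAnnotation":
        return CohortAnnotation(self.table[np.asarray(mask)].reset_index(drop=True))

    def subset_groups(self, groups: Iterable[str]) -> "CohortAnnotation":
        groups = set(groups)
        return self.subset(self.table["group"].isin(groups).to_numpy())

    def sample_field(self, field_name: str) -> pd.Series:
        return self.table.set_index("sample_id")[field_name]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise MatrixIOError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_HEADER_COMMENT}{__version__}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_expression(path: str | Path, expected_scale: str = "counts") -> ExpressionMatrix:
    """Read a genes-rows x samples-columns expression TSV.

    First column holds gene ids; remaining columns are samples.  Duplicate
    gene ids and non-numeric cells are rejected with the offending
    row/column named.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise MatrixIOError(f"{path}: expression table needs gene id + >=1 sample column")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    if genes.duplicated().any():
        dupes = genes[genes.duplicated()].unique().tolist()
        raise MatrixIOError(f"{path}: duplicate gene ids: {dupes[:5]}")
    data = raw.drop(columns=[gene_col])
    numeric = {}
    for col in data.columns:
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & (data[col] != "")
        if bad.any():
            row = genes[bad].iloc[0]
            raise MatrixIOError(
                f"{path}: malformed numeric cell at gene {row!r}, sample {col!r}"
            )
        numeric[col] = converted
    values = pd.DataFrame(numeric)
    values.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(values, scale=expected_scale)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    df = mat.values.copy()
    df.index.name = "gene_id"
    _write_tsv(df, path, index=True)


def read_gene_info(path: str | Path) -> pd.DataFrame:
    """Read gene info TSV with columns gene_id, length_bp, chrom."""
    df = _read_tsv(path)
    needed = {"gene_id", "length_bp", "chrom"}
    if not needed.issubset(df.columns):
        raise MatrixIOError(f"{path}: gene info needs columns {sorted(needed)}")
    df = df.copy()
    df["length_bp"] = pd.to_numeric(df["length_bp"], errors="raise").astype(int)
    if (df["length_bp"] < 1).any():
        bad = df.loc[df["length_bp"] < 1, "gene_id"].iloc[0]
        raise MatrixIOError(f"{path}: non-positive gene length for {bad!r}")
    if df["gene_id"].duplicated().any():
        raise MatrixIOError(f"{path}: duplicate gene ids in gene info")
    return df.set_index("gene_id")


def write_gene_info(info: pd.DataFrame, path: str | Path) -> None:
    df = info.reset_index() if info.index.name == "gene_id" else info
    _write_tsv(df, path)


_NUMERIC_ANN_COLUMNS = ["age_years", "pfs_months", "os_months"]
_INT_ANN_COLUMNS = ["novel_cnv", "os_event", "pfs_event"]


def read_annotation(path: str | Path) -> CohortAnnotation:
    """Read the per-sample clinical annotation TSV.

    Missing values are encoded as literal ``NA`` and surface as NaN in
    numeric columns; downstream survival operations drop and count them.
    """
    df = _read_tsv(path)
    df = df.replace("NA", np.nan)
    for col in _NUMERIC_ANN_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _INT_ANN_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    return CohortAnnotation(df)


def write_annotation(ann: CohortAnnotation, path: str | Path) -> None:
    df = ann.table.copy()
    # literal NA for missing clinical fields
    _write_tsv(df.fillna("NA"), path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB member..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixIOError(f"{path}:{lineno}: GMT line needs name, desc, >=1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise MatrixIOError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def pair_index(ann: CohortAnnotation) -> list[tuple[str, str, str]]:
    """Return (patient_id, primary sample, relapse sample) for complete pairs.

    Patients with only one timepoint are excluded with a logged warning;
    two samples at the same timepoint for one patient is an error.
    Output is ordered by patient id, so repeated calls are deterministic.
    """
    out: list[tuple[str, str, str]] = []
    for patient, sub in sorted(ann.table.groupby("patient_id"), key=lambda kv: str(kv[0])):
        by_tp = {tp: sub.loc[sub["timepoint"] == tp, "sample_id"].tolist() for tp in VALID_TIMEPOINTS}
        for tp, samples in by_tp.items():
            if len(samples) > 1:
                raise MatrixIOError(
                    f"patient {patient!r} has {len(samples)} {tp} samples; pairing ambiguous"
                )
        if by_tp["primary"] and by_tp["relapse"]:
            out.append((str(patient), by_tp["primary"][0], by_tp["relapse"][0]))
        else:
            logger.warning("patient %s lacks a complete primary/relapse pair; excluded", patient)
    return out


def summarize_cohort(ann: CohortAnnotation) -> dict[str, float]:
    """Patient-level cohort summary.

    Reports the relapse-pattern distribution (percent of pairs with local,
    distant and combined recurrences) and the molecular-group conservation
    rate (percent of pairs whose primary and relapse samples carry the same
    group label), along with per-group pair counts.
    """
    pairs = pair_index(ann)
    if not pairs:
        raise MatrixIOError("no complete pairs to summarize")
    tab = ann.table.set_index("sample_id")
    n = len(pairs)
    pattern_counts: dict[str, int] = {}
    conserved = 0
    group_counts: dict[str, int] = {}
    for _, prim, rel in pairs:
        pattern = tab.loc[rel, "relapse_pattern"]
        if pd.isna(pattern):
            pattern = tab.loc[prim, "relapse_pattern"]
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
        g_prim, g_rel = tab.loc[prim, "group"], tab.loc[rel, "group"]
        group_counts[g_prim] = group_counts.get(g_prim, 0) + 1
        if g_prim == g_rel:
            conserved += 1
    summary: dict[str, float] = {"n_pairs": float(n)}
    for pattern, count in sorted(pattern_counts.items()):
        summary[f"pct_{pattern}"] = 100.0 * count / n
    for group, count in sorted(group_counts.items()):
        summary[f"n_pairs_{group}"] = float(count)
    summary["pct_group_conserved"] = 100.0 * conserved / n
    return summary
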