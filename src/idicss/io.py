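"""Shared data model: expression / mutation / clinical containers, readers, and cohort alignment.

All tabular formats are plain TSV (or CSV) with a header row; gene sets are
GMT; protein--protein interaction (PPI) networks are two-column edge lists.
Matrices are held as :class:`pandas.DataFrame` with genes as rows and samples
as columns, expression on a log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("idicss")

#: MAF Variant_Classification values counted as non-silent.
DEFAULT_NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: TCGA-style sample barcode truncation length.
DEFAULT_BARCODE_LENGTH = 15

DAYS_PER_MONTH = 30.44


class SchemaError(ValueError):
    """Input file violates the expected schema."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()
        raise ValueError(f"duplicate {what} IDs: {dup[:5]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """Log-scale normalized expression, genes x samples.

    Invariants: unique gene and sample IDs, no missing values, dimensions
    consistent with the ID lists.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.data.size == 0:
            raise ValueError("empty expression matrix")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values after loading")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: list[str]) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(self.data.loc[:, samples].copy())


@dataclass
class MutationMatrix:
    """Binary gene x sample matrix; 1 = sample carries a non-silent somatic mutation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        self.data = self.data.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, samples: list[str]) -> "MutationMatrix":
        sub = self.data.reindex(columns=samples, fill_value=0)
        return MutationMatrix(sub)


@dataclass
class ClinicalTable:
    """Per-sample clinical endpoints.

    Columns: ``os_time`` (days, >= 0), ``os_event`` (0/1); optional
    ``pfs_time``/``pfs_event`` with the same semantics and a ``response``
    category (CR/PR/SD/PD or responder/non-responder).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        for tcol, ecol in (("os_time", "os_event"), ("pfs_time", "pfs_event")):
            if tcol not in self.data.columns:
                continue
            times = self.data[tcol].astype(float)
            if (times.dropna() < 0).any():
                raise ValueError(f"{tcol} contains negative times")
            events = self.data[ecol].dropna()
            if not events.isin([0, 1]).all():
                raise ValueError(f"{ecol} must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, samples: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[samples].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. immune signatures), names unique, sets non-empty."""

    sets: dict[str, frozenset[str]]
    provenance: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for genes in self.sets.values():
            out = out | genes
        return out


@dataclass
class CohortBundle:
    """Aligned expression + optional mutations + clinical data for one cohort."""

    expression: GeneExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationMatrix | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return self.expression.samples


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, comment="#", **kwargs)


def read_expression(
    path: str | Path,
    *,
    log_transform: bool = False,
    drop_zero_variance: bool = True,
) -> GeneExpressionMatrix:
    """Load a gene x sample expression TSV/CSV.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean; missing values are imputed with the gene-wise median; zero-variance
    genes are dropped; ``log_transform`` applies log2(x+1) for inputs still on
    the linear scale.
    """
    df = _read_table(path)
    if df.size == 0:
        raise ValueError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        bad = _locate_non_numeric(df)
        raise SchemaError(f"{path}: non-numeric cell at {bad}") from exc
    df.index = df.index.astype(str)

    # collapse duplicate gene symbols: keep the row with the highest mean
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]

    if df.isna().any().any():
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)

    if log_transform:
        df = np.log2(df + 1.0)

    if drop_zero_variance:
        var = df.var(axis=1, ddof=0)
        dropped = int((var == 0).sum())
        if dropped:
            logger.info("dropping %d zero-variance genes", dropped)
        df = df.loc[var > 0]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes left after filtering")
    return GeneExpressionMatrix(df.sort_index())


def _locate_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            return f"row {row!r}, column {col!r}"
    return "unknown position"


def write_matrix(data: pd.DataFrame, path: str | Path, *, provenance: str = "idicss") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        data.to_csv(fh, sep="\t")


def read_maf(
    path: str | Path,
    nonsilent_classes: frozenset[str] | set[str] = DEFAULT_NONSILENT_CLASSES,
    *,
    barcode_length: int | None = DEFAULT_BARCODE_LENGTH,
) -> MutationMatrix:
    """Binarize a MAF: cell (gene, sample) = 1 iff >= 1 non-silent record exists."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: MAF missing columns {sorted(missing)}")
    if df.shape[0] == 0:
        logger.warning("%s: MAF has no records; returning 0-gene matrix", path)
        return MutationMatrix(pd.DataFrame(dtype=int))
    df = df[df["Variant_Classification"].isin(nonsilent_classes)]
    samples = df["Tumor_Sample_Barcode"]
    if barcode_length is not None:
        samples = samples.str.slice(0, barcode_length)
    flat = pd.crosstab(df["Hugo_Symbol"], samples)
    binary = (flat > 0).astype(int)
    binary.index.name = None
    binary.columns.name = None
    return MutationMatrix(binary.sort_index())


def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    """Load a precomputed binary gene x sample matrix."""
    df = _read_table(path)
    df.index = df.index.astype(str)
    return MutationMatrix(df)


def read_clinical(
    path: str | Path, *, time_unit: str = "days"
) -> ClinicalTable:
    """Load a clinical TSV indexed by sample ID; months are converted to days."""
    df = _read_table(path)
    df.index = df.index.astype(str)
    if time_unit not in ("days", "months"):
        raise ValueError("time_unit must be 'days' or 'months'")
    if time_unit == "months":
        for col in ("os_time", "pfs_time"):
            if col in df.columns:
                df[col] = df[col].astype(float) * DAYS_PER_MONTH
    return ClinicalTable(df)


def read_gmt(path: str | Path, *, provenance: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(
        sets, provenance=provenance or str(path), descriptions=descriptions
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, collection.provenance or "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_ppi(path: str | Path) -> nx.Graph:
    """Load an undirected, unweighted PPI edge list (two-column TSV, no header required)."""
    edges = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if edges.shape[1] < 2:
        raise SchemaError(f"{path}: PPI edge list needs two columns")
    if {"gene_a", "gene_b"} <= set(edges.iloc[0]):
        edges = edges.iloc[1:]
    graph = nx.Graph()
    graph.add_edges_from(
        (a, b) for a, b in zip(edges[0], edges[1]) if a != b
    )
    return graph


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in graph.edges():
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# Cohort alignment
# ---------------------------------------------------------------------------


def align_cohort(
    expression: GeneExpressionMatrix,
    clinical: ClinicalTable,
    mutations: MutationMatrix | None = None,
    metadata: Mapping[str, str] | None = None,
) -> CohortBundle:
    """Restrict all tables to the samples present in both expression and clinical.

    Mutation samples absent from the expression matrix are dropped; expression
    samples without mutation calls get all-zero mutation columns. Idempotent.
    """
    keep = [s for s in expression.samples if s in set(clinical.samples)]
    if not keep:
        raise ValueError("no samples shared between expression and clinical tables")
    n_dropped = len(expression.samples) - len(keep)
    logger.info("align_cohort: kept %d samples, dropped %d", len(keep), n_dropped)
    bundle = CohortBundle(
        expression=expression.subset_samples(keep),
        clinical=clinical.subset_samples(keep),
        mutations=mutations.subset_samples(keep) if mutations is not None else None,
        metadata=dict(metadata or {}),
    )
    if mutations is None:
        bundle.metadata.setdefault("mutations", "absent")
    return bundle
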