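"""Gene-cluster presence/absence matrices and pangenome set algebra.

A pangenome is summarized as a genomes x gene-clusters copy-count matrix.
Presence means copy count >= 1; single-copy means exactly 1. The set
operations here (core, group-exclusive core, single-copy core) are the
primitives for comparing host genomes grouped by epibiont-susceptibility
phenotype (resistant / permissive / nonpermissive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RESISTANT",
    "PERMISSIVE",
    "NONPERMISSIVE",
    "GROUPS",
    "TableDialect",
    "GeneClusterMatrix",
    "PhenotypeMap",
    "FormatError",
    "load_gene_cluster_table",
    "load_phenotype_map",
    "core_clusters",
    "exclusive_core",
    "single_copy_core",
]

RESISTANT = "resistant"
PERMISSIVE = "permissive"
NONPERMISSIVE = "nonpermissive"
#: canonical group order used throughout reports
GROUPS = (RESISTANT, NONPERMISSIVE, PERMISSIVE)


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


@dataclass(frozen=True)
class TableDialect:
    """Column names of a gene-cluster membership table.

    Defaults follow the anvi'o pangenome summary header. The accession and
    annotation columns are optional; either may be absent from the file.
    """

    gene_col: str = "gene_callers_id"
    genome_col: str = "genome_name"
    cluster_col: str = "gene_cluster_id"
    accession_col: str = "accession"
    annotation_col: str = "function"


@dataclass
class GeneClusterMatrix:
    """Genomes x gene-clusters copy-count matrix with cluster annotations.

    Parameters
    ----------
    genomes
        Ordered genome names (rows). Unique.
    clusters
        Ordered gene-cluster ids (columns). Unique.
    counts
        Integer array of shape ``(len(genomes), len(clusters))``; entry
        ``[i, j]`` is the number of genes of cluster ``j`` called in genome
        ``i``. Every cluster must be present (count >= 1) in at least one
        genome.
    functions
        Map cluster id -> set of ``(accession, annotation)`` pairs; may be
        empty for unannotated clusters.
    """

    genomes: list[str]
    clusters: list[str]
    counts: np.ndarray
    functions: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.genomes), len(self.clusters)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genomes)} genomes x {len(self.clusters)} clusters"
            )
        if (self.counts < 0).any():
            raise ValueError("copy counts must be non-negative")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("genome names must be unique")
        if len(set(self.clusters)) != len(self.clusters):
            raise ValueError("cluster ids must be unique")
        if self.counts.size and not (self.counts >= 1).any(axis=0).all():
            empty = [c for c, any_ in zip(self.clusters, (self.counts >= 1).any(axis=0)) if not any_]
            raise ValueError(f"clusters with no member genes: {empty[:5]}")
        self._genome_index = {g: i for i, g in enumerate(self.genomes)}
        self._cluster_index = {c: j for j, c in enumerate(self.clusters)}

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence/absence view (count >= 1)."""
        return self.counts >= 1

    def genome_rows(self, genome_set: Iterable[str]) -> np.ndarray:
        """Row indices for a set of genome names (sorted for determinism)."""
        try:
            return np.array(sorted(self._genome_index[g] for g in genome_set), dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown genome: {exc.args[0]!r}") from None

    def cluster_functions(self, cluster_id: str) -> set[tuple[str, str]]:
        return self.functions.get(cluster_id, set())

    def subset_genomes(self, genome_set: Iterable[str]) -> "GeneClusterMatrix":
        """Restrict to a genome subset, dropping clusters that become empty."""
        rows = self.genome_rows(genome_set)
        sub = self.counts[rows]
        keep = (sub >= 1).any(axis=0)
        clusters = [c for c, k in zip(self.clusters, keep) if k]
        return GeneClusterMatrix(
            genomes=[self.genomes[i] for i in rows],
            clusters=clusters,
            counts=sub[:, keep],
            functions={c: set(self.functions.get(c, set())) for c in clusters},
        )


@dataclass
class PhenotypeMap:
    """Genome -> phenotype group assignment.

    Groups are ``resistant``, ``permissive`` and ``nonpermissive``;
    ``susceptible`` is the derived union of the latter two.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g: p for g, p in self.assignments.items() if p not in GROUPS}
        if bad:
            raise ValueError(f"unknown phenotype group(s): {bad}")

    def group(self, genome: str) -> str:
        try:
            return self.assignments[genome]
        except KeyError:
            raise KeyError(f"genome {genome!r} has no phenotype assignment") from None

    def genomes_in(self, group: str) -> set[str]:
        if group == "susceptible":
            return self.susceptible
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return {g for g, p in self.assignments.items() if p == group}

    @property
    def susceptible(self) -> set[str]:
        return {g for g, p in self.assignments.items() if p in (PERMISSIVE, NONPERMISSIVE)}

    def check_covers(self, genomes: Iterable[str], allow_unlabeled: bool = False) -> list[str]:
        """Verify every genome is labeled.

        Returns the list of unlabeled genomes if ``allow_unlabeled`` (caller
        drops them); otherwise raises ``KeyError`` on the first gap.
        """
        missing = [g for g in genomes if g not in self.assignments]
        if missing and not allow_unlabeled:
            raise KeyError(f"genomes without phenotype assignment: {missing}")
        return missing


def load_gene_cluster_table(path, dialect: TableDialect | None = None) -> GeneClusterMatrix:
    """Read a tab-separated gene-cluster membership table.

    One row per gene: gene id, genome, gene-cluster id, and optional
    function accession/annotation columns. Copy counts are aggregated per
    (genome, cluster); genomes and clusters are ordered lexicographically
    so loading is independent of row order.
    """
    dialect = dialect or TableDialect()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty gene-cluster table: {path}") from None
    for col in (dialect.gene_col, dialect.genome_col, dialect.cluster_col):
        if col not in df.columns:
            raise FormatError(f"gene-cluster table missing required column {col!r}")
    if df.empty:
        raise FormatError(f"gene-cluster table has no data rows: {path}")
    if df[dialect.gene_col].duplicated().any():
        dup = df.loc[df[dialect.gene_col].duplicated(), dialect.gene_col].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r} in gene-cluster table")

    genomes = sorted(df[dialect.genome_col].unique())
    clusters = sorted(df[dialect.cluster_col].unique())
    gi = {g: i for i, g in enumerate(genomes)}
    ci = {c: j for j, c in enumerate(clusters)}
    counts = np.zeros((len(genomes), len(clusters)), dtype=np.int64)
    np.add.at(
        counts,
        (df[dialect.genome_col].map(gi).to_numpy(), df[dialect.cluster_col].map(ci).to_numpy()),
        1,
    )

    functions: dict[str, set[tuple[str, str]]] = {}
    has_acc = dialect.accession_col in df.columns
    has_ann = dialect.annotation_col in df.columns
    if has_acc or has_ann:
        acc = df[dialect.accession_col] if has_acc else pd.Series("", index=df.index)
        ann = df[dialect.annotation_col] if has_ann else pd.Series("", index=df.index)
        for cluster, a, t in zip(df[dialect.cluster_col], acc.fillna(""), ann.fillna("")):
            if a or t:
                functions.setdefault(cluster, set()).add((str(a), str(t)))
    return GeneClusterMatrix(genomes=genomes, clusters=clusters, counts=counts, functions=functions)


def load_phenotype_map(path) -> PhenotypeMap:
    """Read a two-column tab-separated genome -> group table (header row)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty phenotype map: {path}") from None
    if df.shape[1] < 2:
        raise FormatError("phenotype map needs two columns: genome, group")
    genome_col, group_col = df.columns[:2]
    if df[genome_col].duplicated().any():
        dup = df.loc[df[genome_col].duplicated(), genome_col].iloc[0]
        raise FormatError(f"genome {dup!r} assigned twice in phenotype map")
    return PhenotypeMap(assignments=dict(zip(df[genome_col], df[group_col].str.strip().str.lower())))


def core_clusters(m: GeneClusterMatrix, genome_set: Iterable[str]) -> set[str]:
    """Clusters present (count >= 1) in every genome of ``genome_set``."""
    rows = m.genome_rows(_nonempty(genome_set))
    mask = (m.counts[rows] >= 1).all(axis=0)
    return {c for c, k in zip(m.clusters, mask) if k}


def exclusive_core(m: GeneClusterMatrix, in_group: Iterable[str], out_group: Iterable[str]) -> set[str]:
    """Clusters present in every in-group genome and absent from every out-group genome."""
    in_set, out_set = set(in_group), set(out_group)
    if not in_set or not out_set:
        raise ValueError("in_group and out_group must both be nonempty")
    if in_set & out_set:
        raise ValueError(f"in_group and out_group overlap: {sorted(in_set & out_set)}")
    rows_in = m.genome_rows(in_set)
    rows_out = m.genome_rows(out_set)
    mask = (m.counts[rows_in] >= 1).all(axis=0) & (m.counts[rows_out] == 0).all(axis=0)
    return {c for c, k in zip(m.clusters, mask) if k}


def single_copy_core(m: GeneClusterMatrix, genome_set: Iterable[str]) -> set[str]:
    """Clusters with exactly one gene copy in every genome of ``genome_set``.

    These are the clusters suitable for per-cluster gene-tree inference:
    one sequence per genome, no paralogs.
    """
    rows = m.genome_rows(_nonempty(genome_set))
    mask = (m.counts[rows] == 1).all(axis=0)
    return {c for c, k in zip(m.clusters, mask) if k}


def _nonempty(genome_set: Iterable[str]) -> set[str]:
    s = set(genome_set)
    if not s:
        raise ValueError("genome_set must be nonempty")
    return s
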