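"""Readers and writers for the pipeline's plain-text formats.

Formats: gene-cluster membership table (TSV, one row per gene), phenotype
map (TSV), Newick tree directory (one ``<cluster_id>.nwk`` per gene
cluster), passage-series table (CSV with dose-0 rows as the uninfected
control), enrichment and screen reports (TSV), truth/manifest (JSON).
All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import PassageSeries, PhenotypeCall
from .pangenome import GeneClusterMatrix, PhenotypeMap, TableDialect, FormatError
from .trees import LabeledGeneTree, ScreenResult, parse_labeled_tree

__all__ = [
    "atomic_write_text",
    "write_gene_cluster_table",
    "write_phenotype_map",
    "write_tree_dir",
    "read_tree_dir",
    "write_passage_csv",
    "read_passage_csv",
    "write_cluster_sets",
    "write_screen_report",
    "write_calls_table",
    "write_json",
]

PASSAGE_COLUMNS = ["strain", "dose", "passage", "density", "parasite_score", "total_cfu", "irregular_cfu"]


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_gene_cluster_table(m: GeneClusterMatrix, path, dialect: TableDialect | None = None) -> None:
    """Emit one row per gene copy, with synthetic sequential gene ids."""
    dialect = dialect or TableDialect()
    lines = [
        "\t".join([dialect.gene_col, dialect.genome_col, dialect.cluster_col,
                   dialect.accession_col, dialect.annotation_col])
    ]
    gene_id = 0
    for i, genome in enumerate(m.genomes):
        for j, cluster in enumerate(m.clusters):
            funcs = sorted(m.functions.get(cluster, set())) or [("", "")]
            for k in range(int(m.counts[i, j])):
                acc, ann = funcs[k % len(funcs)]  # cycle annotations over gene copies
                lines.append(f"g{gene_id:08d}\t{genome}\t{cluster}\t{acc}\t{ann}")
                gene_id += 1
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_phenotype_map(ph: PhenotypeMap, path) -> None:
    lines = ["genome\tphenotype"]
    lines += [f"{g}\t{p}" for g, p in sorted(ph.assignments.items())]
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_tree_dir(trees: Sequence[LabeledGeneTree], directory) -> None:
    """One Newick file per tree, named ``<cluster_id>.nwk``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in trees:
        newick = t.tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        atomic_write_text(directory / f"{t.cluster_id}.nwk", newick)


def read_tree_dir(directory, ph: PhenotypeMap) -> list[LabeledGeneTree]:
    directory = Path(directory)
    trees = []
    for path in sorted(directory.glob("*.nwk")):
        trees.append(parse_labeled_tree(path.read_text(), ph, cluster_id=path.stem))
    return trees


def write_passage_csv(series: Iterable[PassageSeries], path) -> None:
    """Passage table with per-strain dose-0 control rows.

    Each series contributes its infected rows plus (once per strain) the
    matching control series flagged by dose 0.
    """
    frames = []
    controls_done = set()
    for s in series:
        df = pd.DataFrame({
            "strain": s.strain, "dose": s.dose, "passage": s.passage,
            "density": s.density, "parasite_score": s.parasite_score,
            "total_cfu": s.total_cfu if s.total_cfu is not None else np.nan,
            "irregular_cfu": s.irregular_cfu if s.irregular_cfu is not None else np.nan,
        })
        frames.append(df)
        if s.strain not in controls_done and s.dose > 0:
            frames.append(pd.DataFrame({
                "strain": s.strain, "dose": 0.0, "passage": s.passage,
                "density": s.control_density, "parasite_score": 0.0,
                "total_cfu": np.nan, "irregular_cfu": np.nan,
            }))
            controls_done.add(s.strain)
    out = pd.concat(frames, ignore_index=True)[PASSAGE_COLUMNS]
    tmp = Path(str(path) + ".tmp")
    out.to_csv(tmp, index=False)
    os.replace(tmp, path)


def read_passage_csv(path) -> list[PassageSeries]:
    """Reconstruct per-(strain, dose) series; dose-0 rows are the control."""
    df = pd.read_csv(path)
    missing = [c for c in PASSAGE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"passage table missing column(s): {missing}")
    series = []
    for (strain, dose), grp in df[df["dose"] > 0].groupby(["strain", "dose"], sort=True):
        grp = grp.sort_values("passage")
        ctrl = df[(df["strain"] == strain) & (df["dose"] == 0)].sort_values("passage")
        if len(ctrl) != len(grp) or (ctrl["passage"].to_numpy() != grp["passage"].to_numpy()).any():
            raise FormatError(f"control (dose 0) rows for strain {strain!r} do not cover its passages")
        has_cfu = grp["total_cfu"].notna().all() if "total_cfu" in grp else False
        series.append(PassageSeries(
            strain=str(strain), dose=float(dose),
            passage=grp["passage"].to_numpy(),
            density=grp["density"].to_numpy(),
            parasite_score=grp["parasite_score"].to_numpy(),
            control_density=ctrl["density"].to_numpy(),
            total_cfu=grp["total_cfu"].to_numpy() if has_cfu else None,
            irregular_cfu=grp["irregular_cfu"].to_numpy() if has_cfu else None,
        ))
    return series


def write_cluster_sets(sets: dict[str, set[str]], directory) -> None:
    """One single-column listing per set plus a TSV of set sizes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = ["set\tsize"]
    for name in sorted(sets):
        atomic_write_text(directory / f"{name}.txt", "\n".join(sorted(sets[name])) + "\n")
        summary.append(f"{name}\t{len(sets[name])}")
    atomic_write_text(directory / "set_sizes.tsv", "\n".join(summary) + "\n")


def write_screen_report(results: Sequence[ScreenResult], path) -> None:
    lines = ["gene_cluster\tconstraint\tn_internal_edges\tfunctions"]
    for r in results:
        funcs = ";".join(f"{a}|{t}" for a, t in sorted(r.functions))
        lines.append(f"{r.cluster_id}\t{r.matched or 'none'}\t{r.n_internal_edges}\t{funcs}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_calls_table(calls: Sequence[tuple[float, PhenotypeCall]], path) -> None:
    lines = ["strain\tdose\tcall\tcrash_point\tcrash_duration"]
    for dose, c in calls:
        cp = "" if c.crash_point is None else str(c.crash_point)
        cd = "" if c.crash_duration is None else str(c.crash_duration)
        lines.append(f"{c.strain}\t{dose:g}\t{c.call}\t{cp}\t{cd}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
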