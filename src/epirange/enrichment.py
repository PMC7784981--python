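"""Functional enrichment across phenotype groups.

Each annotated function is tested for differential presence across the
phenotype groups with the Rao score statistic, which for a binary outcome
(function present / absent) against a categorical predictor (group) equals
the Pearson chi-square statistic on the 2 x G contingency table. A function
perfectly confined to one group boundary scores N, the number of labeled
genomes. P-values come from the chi-square upper tail with G-1 degrees of
freedom; q-values are Benjamini-Hochberg adjusted over the full tested
universe. Each function is also assigned the set of groups in which a
majority of genomes carry it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pangenome import GROUPS, GeneClusterMatrix, PhenotypeMap

__all__ = [
    "FunctionPresenceProfile",
    "EnrichmentRecord",
    "function_presence",
    "enrichment_score",
    "enrichment_score_vector",
    "enrichment_pvalue",
    "bh_fdr",
    "associated_groups",
    "run_enrichment",
    "enrichment_table",
]


@dataclass
class FunctionPresenceProfile:
    """Per-function presence pattern across labeled genomes."""

    function: tuple[str, str]  # (accession, annotation text)
    presence: dict[str, bool]  # genome -> carries >=1 gene with this function
    per_group_counts: dict[str, tuple[int, int]]  # group -> (n_present, n_total)


@dataclass
class EnrichmentRecord:
    """Scored enrichment result for one function."""

    function: tuple[str, str]
    score: float
    p_value: float
    q_value: float
    fractions: dict[str, float]
    per_group_counts: dict[str, tuple[int, int]]
    associated_groups: set[str]


def function_presence(
    m: GeneClusterMatrix,
    ph: PhenotypeMap,
    annotation_source: str = "accession",
    allow_unlabeled: bool = False,
) -> list[FunctionPresenceProfile]:
    """Collapse cluster annotations into per-function presence profiles.

    A genome "has" a function iff at least one gene cluster annotated with
    that function is present (count >= 1) in the genome. ``annotation_source``
    selects the aggregation key: ``"accession"`` or ``"annotation"`` text.
    """
    if annotation_source not in ("accession", "annotation"):
        raise ValueError("annotation_source must be 'accession' or 'annotation'")
    unlabeled = set(ph.check_covers(m.genomes, allow_unlabeled=allow_unlabeled))
    if unlabeled:
        warnings.warn(f"dropping {len(unlabeled)} unlabeled genome(s): {sorted(unlabeled)}")
    genomes = [g for g in m.genomes if g not in unlabeled]
    if not m.functions:
        warnings.warn("no function annotations in matrix; empty enrichment result")
        return []

    # function key -> representative (accession, annotation) and member clusters
    key_of = (lambda f: f[0]) if annotation_source == "accession" else (lambda f: f[1])
    members: dict[str, list[int]] = {}
    rep: dict[str, tuple[str, str]] = {}
    for j, cluster in enumerate(m.clusters):
        for func in m.functions.get(cluster, ()):
            k = key_of(func)
            if not k:
                continue
            members.setdefault(k, []).append(j)
            rep.setdefault(k, func)

    rows = m.genome_rows(genomes)
    presence = m.counts[rows] >= 1
    group_of = {g: ph.group(g) for g in genomes}
    totals = {grp: sum(1 for g in genomes if group_of[g] == grp) for grp in GROUPS}

    profiles = []
    for k in sorted(members):
        has = presence[:, members[k]].any(axis=1)
        by_genome = {g: bool(h) for g, h in zip([m.genomes[i] for i in rows], has)}
        counts = {
            grp: (sum(1 for g, h in by_genome.items() if h and group_of[g] == grp), totals[grp])
            for grp in GROUPS
        }
        profiles.append(
            FunctionPresenceProfile(function=rep[k], presence=by_genome, per_group_counts=counts)
        )
    return profiles


def enrichment_score_vector(n_present: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    """Pearson chi-square scores for many functions at once.

    Parameters
    ----------
    n_present
        Array of shape (n_functions, G): genomes carrying the function per group.
    n_total
        Array of shape (G,): group sizes, all >= 1.

    Returns the chi-square statistic of each 2 x G (present/absent x group)
    table; 0 where the function is present in all or no genomes (no
    association is testable).

    Notes
    -----
    With ``p`` the overall presence fraction, the statistic reduces to
    ``sum_g (k_g - n_g p)^2 / (n_g p (1 - p))`` — both cells of a column
    share the same squared residual.
    """
    k = np.atleast_2d(np.asarray(n_present, dtype=float))
    n = np.asarray(n_total, dtype=float)
    if (n < 1).any():
        raise ValueError("every group must contain at least one genome")
    if k.shape[1] != n.shape[0]:
        raise ValueError("n_present and n_total disagree on the number of groups")
    if (k < 0).any() or (k > n).any():
        raise ValueError("need 0 <= n_present <= n_total in every group")
    N = n.sum()
    p = k.sum(axis=1) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        score = ((k - n * p[:, None]) ** 2 / (n * (p * (1 - p))[:, None])).sum(axis=1)
    score[(p == 0) | (p == 1)] = 0.0
    return score


def enrichment_score(per_group_counts: Mapping[str, tuple[int, int]]) -> float:
    """Rao score statistic of group/function-presence association.

    ``per_group_counts`` maps group -> (n_present, n_total). Requires at
    least two groups. Returns 0 when the function is present in all or no
    genomes.
    """
    if len(per_group_counts) < 2:
        raise ValueError("need at least two groups")
    groups = sorted(per_group_counts)
    k = np.array([[per_group_counts[g][0] for g in groups]])
    n = np.array([per_group_counts[g][1] for g in groups])
    return float(enrichment_score_vector(k, n)[0])


def enrichment_pvalue(score: float, n_groups: int) -> float:
    """Upper-tail chi-square probability with ``n_groups - 1`` df."""
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if score < 0:
        raise ValueError("score must be non-negative")
    return float(stats.chi2.sf(score, df=n_groups - 1))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def associated_groups(fractions: Mapping[str, float], cutoff: float = 0.5) -> set[str]:
    """Groups in which at least ``cutoff`` of genomes carry the function."""
    if any(f < 0 or f > 1 for f in fractions.values()):
        raise ValueError("fractions must lie in [0, 1]")
    return {g for g, f in fractions.items() if f >= cutoff}


def run_enrichment(
    m: GeneClusterMatrix,
    ph: PhenotypeMap,
    annotation_source: str = "accession",
    allow_unlabeled: bool = False,
    group_cutoff: float = 0.5,
    top_n: int | None = None,
) -> list[EnrichmentRecord]:
    """Score every annotated function and rank by enrichment.

    q-values are BH-adjusted over all tested functions; the ranking is by
    descending score with ties broken lexicographically on the accession.
    ``top_n`` truncates the ranked list after adjustment.
    """
    profiles = function_presence(m, ph, annotation_source, allow_unlabeled)
    if not profiles:
        return []
    groups = sorted(profiles[0].per_group_counts)
    k = np.array([[pr.per_group_counts[g][0] for g in groups] for pr in profiles])
    n = np.array([profiles[0].per_group_counts[g][1] for g in groups])
    scores = enrichment_score_vector(k, n)
    pvals = stats.chi2.sf(scores, df=len(groups) - 1)
    qvals = bh_fdr(pvals)
    records = []
    for pr, s, p, q in zip(profiles, scores, pvals, qvals):
        fr = {
            g: pr.per_group_counts[g][0] / pr.per_group_counts[g][1]
            for g in pr.per_group_counts
        }
        records.append(
            EnrichmentRecord(
                function=pr.function,
                score=float(s),
                p_value=float(p),
                q_value=float(q),
                fractions=fr,
                per_group_counts=dict(pr.per_group_counts),
                associated_groups=associated_groups(fr, cutoff=group_cutoff),
            )
        )
    records.sort(key=lambda r: (-r.score, r.function[0]))
    return records[:top_n] if top_n is not None else records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular report: one row per function, fractions as ``x/y`` strings."""
    rows = []
    for r in records:
        row = {
            "accession": r.function[0],
            "function": r.function[1],
            "enrichment_score": r.score,
            "p_value": r.p_value,
            "q_value": r.q_value,
        }
        for g in GROUPS:
            if g in r.per_group_counts:
                k, n = r.per_group_counts[g]
                row[f"observation_{g}"] = f"{k}/{n}"
        row["associated_groups"] = ",".join(sorted(r.associated_groups))
        rows.append(row)
    return pd.DataFrame(rows)
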