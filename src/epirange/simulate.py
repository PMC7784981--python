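"""Truth-known synthetic data for the host-range analysis pipeline.

Three generators mirror the three kinds of study input:

- :func:`simulate_pangenome` draws a genomes x gene-clusters matrix with
  planted core and group-exclusive clusters over a background of
  independent presence/absence noise, for 23 genomes in three phenotype
  groups (10 resistant / 3 nonpermissive / 10 permissive) by default;
- :func:`simulate_gene_trees` draws per-cluster gene trees that are either
  concordant with the phenotype grouping (groups monophyletic, resistant
  sister to nonpermissive) or random joins of all leaves, with optional
  polytomies;
- :func:`simulate_passages` runs a minimal discrete-passage host/parasite
  model producing growth/crash/recovery curves whose crash timing falls
  with parasite dose.

Every generator is a pure function of its config (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .growth import PassageSeries
from .pangenome import (
    GROUPS,
    NONPERMISSIVE,
    PERMISSIVE,
    RESISTANT,
    GeneClusterMatrix,
    PhenotypeMap,
)
from .trees import LabeledGeneTree

__all__ = [
    "PangenomeSimConfig",
    "TreeSimConfig",
    "PassageSimConfig",
    "default_genomes",
    "simulate_pangenome",
    "simulate_gene_trees",
    "simulate_passages",
    "PHENOTYPE_PARAMS",
]


def default_genomes(
    n_resistant: int = 10, n_nonpermissive: int = 3, n_permissive: int = 10
) -> dict[str, str]:
    """Genome -> group map with the default 10/3/10 study design."""
    names = {}
    for prefix, group, n in (
        ("R", RESISTANT, n_resistant),
        ("NP", NONPERMISSIVE, n_nonpermissive),
        ("P", PERMISSIVE, n_permissive),
    ):
        for i in range(1, n + 1):
            names[f"{prefix}{i:02d}"] = group
    return names


# ---------------------------------------------------------------------------
# pangenome simulation
# ---------------------------------------------------------------------------

@dataclass
class PangenomeSimConfig:
    """Design of a synthetic group-structured pangenome.

    Defaults emulate the 23-genome study pangenome: 12,372 gene clusters in
    total, 346 core to all genomes, 464 exclusive to the 13 susceptible
    genomes, 51 / 28 exclusive to the resistant / nonpermissive groups, and
    enough background clusters at presence probability ``noise_theta`` to
    put each genome's repertoire in the ~1700-2800 band.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {RESISTANT: 10, NONPERMISSIVE: 3, PERMISSIVE: 10}
    )
    n_core: int = 346
    n_exclusive: dict[str, int] = field(
        default_factory=lambda: {
            "susceptible": 464,
            RESISTANT: 51,
            NONPERMISSIVE: 28,
            PERMISSIVE: 40,
        }
    )
    n_noise: int = 11443
    noise_theta: float = 0.15
    multi_copy_fraction: float = 0.15  # of core clusters: one genome carries 2 copies
    annotate_noise: bool = True  # give every noise cluster its own function
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_theta <= 1:
            raise ValueError("noise_theta must lie in [0, 1]")
        if min(self.group_sizes.values(), default=1) < 0 or self.n_core < 0 or self.n_noise < 0:
            raise ValueError("all counts must be >= 0")
        for key, n in self.n_exclusive.items():
            if n < 0:
                raise ValueError("exclusive counts must be >= 0")
            groups = (PERMISSIVE, NONPERMISSIVE) if key == "susceptible" else (key,)
            for g in groups:
                if n > 0 and self.group_sizes.get(g, 0) == 0:
                    raise ValueError(f"planting for {key!r} references empty group {g!r}")


def simulate_pangenome(
    cfg: PangenomeSimConfig,
) -> tuple[GeneClusterMatrix, PhenotypeMap, dict]:
    """Draw a planted pangenome; returns (matrix, phenotypes, truth record).

    Planted clusters are present in every in-group genome and absent from
    all others; noise clusters are present independently with probability
    ``noise_theta`` (clusters that end up in no genome are redrawn into at
    least one). Each planted cluster carries one unique function; noise
    clusters are annotated when ``annotate_noise``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome_groups: dict[str, str] = {}
    for prefix, group in (("R", RESISTANT), ("NP", NONPERMISSIVE), ("P", PERMISSIVE)):
        for i in range(1, cfg.group_sizes.get(group, 0) + 1):
            genome_groups[f"{prefix}{i:02d}"] = group
    genomes = sorted(genome_groups)
    ph = PhenotypeMap(assignments=genome_groups)
    n_genomes = len(genomes)
    gidx = {g: i for i, g in enumerate(genomes)}

    member_rows = {
        RESISTANT: [gidx[g] for g in genomes if genome_groups[g] == RESISTANT],
        NONPERMISSIVE: [gidx[g] for g in genomes if genome_groups[g] == NONPERMISSIVE],
        PERMISSIVE: [gidx[g] for g in genomes if genome_groups[g] == PERMISSIVE],
    }
    member_rows["susceptible"] = sorted(member_rows[PERMISSIVE] + member_rows[NONPERMISSIVE])

    clusters: list[str] = []
    cols: list[np.ndarray] = []
    functions: dict[str, set[tuple[str, str]]] = {}
    truth: dict = {
        "core": [], "exclusive": {k: [] for k in cfg.n_exclusive}, "noise": [],
        "functions": {"core": [], "exclusive": {k: [] for k in cfg.n_exclusive}, "noise": []},
        "seed": cfg.seed, "noise_theta": cfg.noise_theta,
    }

    def add(cid: str, col: np.ndarray, accession: str, annotation: str) -> None:
        clusters.append(cid)
        cols.append(col)
        functions[cid] = {(accession, annotation)}

    n_multi = int(round(cfg.multi_copy_fraction * cfg.n_core))
    for i in range(cfg.n_core):
        col = np.ones(n_genomes, dtype=np.int64)
        if i < n_multi:  # a paralog in one random genome: core but not single-copy
            col[rng.integers(n_genomes)] = 2
        cid = f"GC_CORE_{i:05d}"
        add(cid, col, f"FC{i:05d}", f"core function {i}")
        truth["core"].append(cid)
        truth["functions"]["core"].append(f"FC{i:05d}")

    for key in sorted(cfg.n_exclusive):
        rows = member_rows[key]
        tag = {"susceptible": "S", RESISTANT: "R", NONPERMISSIVE: "N", PERMISSIVE: "P"}[key]
        for i in range(cfg.n_exclusive[key]):
            col = np.zeros(n_genomes, dtype=np.int64)
            col[rows] = 1
            cid = f"GC_EXCL_{tag}_{i:05d}"
            acc = f"FX{tag}{i:05d}"
            add(cid, col, acc, f"{key}-exclusive function {i}")
            truth["exclusive"][key].append(cid)
            truth["functions"]["exclusive"][key].append(acc)

    if cfg.n_noise:
        noise = (rng.random((n_genomes, cfg.n_noise)) < cfg.noise_theta).astype(np.int64)
        empty = np.flatnonzero(noise.sum(axis=0) == 0)
        noise[rng.integers(n_genomes, size=empty.size), empty] = 1
        for i in range(cfg.n_noise):
            cid = f"GC_NOISE_{i:05d}"
            clusters.append(cid)
            truth["noise"].append(cid)
            if cfg.annotate_noise:
                acc = f"FN{i:05d}"
                functions[cid] = {(acc, f"background function {i}")}
                truth["functions"]["noise"].append(acc)
        cols.append(noise)

    counts = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols]) if cols else \
        np.zeros((n_genomes, 0), dtype=np.int64)
    order = np.argsort(clusters)
    m = GeneClusterMatrix(
        genomes=genomes,
        clusters=[clusters[j] for j in order],
        counts=counts[:, order],
        functions=functions,
    )
    return m, ph, truth


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------

@dataclass
class TreeSimConfig:
    """Design of a synthetic gene-tree collection.

    ``concordant_fraction`` of trees are built by joining random
    within-group subtrees under the phenotype nesting (resistant sister to
    nonpermissive when all three groups are present; permissive vs
    nonpermissive when only the susceptible groups are); the rest join all
    leaves in random order. ``resolution_prob`` is the chance each internal
    edge is kept: 1 gives fully resolved binary trees, lower values
    introduce polytomies by edge contraction.
    """

    leaves: dict[str, str] = field(default_factory=default_genomes)
    n_trees: int = 50
    concordant_fraction: float = 0.5
    resolution_prob: float = 1.0
    branch_length_mean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must lie in [0, 1]")
        if not 0 <= self.resolution_prob <= 1:
            raise ValueError("resolution_prob must lie in [0, 1]")
        if len(self.leaves) < 3:
            raise ValueError("need at least 3 leaves")


def _join_random(nodes: list, rng: np.random.Generator) -> "dendropy.Node":
    """Random sequential pairwise join of subtrees into one root node."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def simulate_gene_trees(cfg: TreeSimConfig) -> tuple[list[LabeledGeneTree], dict]:
    """Draw labeled gene trees; returns (trees, truth record).

    The truth record flags each tree ``concordant`` or ``discordant`` by
    cluster id. Concordant trees remain constraint-compatible after any
    polytomy introduction (contracting edges only loses resolution).
    """
    rng = np.random.default_rng(cfg.seed)
    groups_present = sorted(set(cfg.leaves.values()))
    trees: list[LabeledGeneTree] = []
    truth: dict = {"concordant": [], "discordant": [], "seed": cfg.seed}

    for t in range(cfg.n_trees):
        cluster_id = f"GC_TREE_{t:04d}"
        concordant = bool(rng.random() < cfg.concordant_fraction)
        ns = dendropy.TaxonNamespace()
        leaf_nodes: dict[str, dendropy.Node] = {}
        for name in sorted(cfg.leaves):
            node = dendropy.Node(taxon=ns.new_taxon(name))
            leaf_nodes[name] = node

        if concordant:
            sub = {
                g: _join_random([leaf_nodes[l] for l in sorted(cfg.leaves) if cfg.leaves[l] == g], rng)
                for g in groups_present
            }
            if set(sub) >= {RESISTANT, NONPERMISSIVE, PERMISSIVE}:
                inner = dendropy.Node()
                inner.add_child(sub[RESISTANT])
                inner.add_child(sub[NONPERMISSIVE])
                root = dendropy.Node()
                root.add_child(inner)
                root.add_child(sub[PERMISSIVE])
            else:
                root = dendropy.Node()
                for g in groups_present:
                    root.add_child(sub[g])
        else:
            root = _join_random(list(leaf_nodes.values()), rng)

        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = root
        tree.is_rooted = True
        for edge in tree.preorder_edge_iter():
            edge.length = float(rng.exponential(cfg.branch_length_mean)) if edge.tail_node else None
        if cfg.resolution_prob < 1:
            to_contract = [
                e for e in tree.preorder_edge_iter()
                if e.tail_node is not None and not e.head_node.is_leaf()
                and rng.random() > cfg.resolution_prob
            ]
            for e in to_contract:
                e.head_node.edge.collapse()
        trees.append(
            LabeledGeneTree(cluster_id=cluster_id, tree=tree, leaf_to_group=dict(cfg.leaves))
        )
        truth["concordant" if concordant else "discordant"].append(cluster_id)
    return trees, truth


# ---------------------------------------------------------------------------
# passage simulation
# ---------------------------------------------------------------------------

@dataclass
class PassageSimConfig:
    """Minimal discrete-passage host/parasite model.

    Each 24 h passage integrates (hourly exponential-Euler steps) a
    logistic host culture with two subpopulations — naive hosts and
    damage-resistant variants — plus the per-host parasite load ``lam``
    (epibionts are surface-attached, so the load rides host divisions):

    - ``lam`` multiplies by ``exp(replication * attachment * (1 - lam/cap)
      - decay - g)`` per hour, where ``g`` is the host's current logistic
      growth rate (host division spreads attached parasites over more
      cells); the 1:10 dilution leaves ``lam`` unchanged;
    - per-capita naive death is ``damage * lam**damage_exponent`` (capped):
      killing requires several parasites per host, so the death rate turns
      on sharply once the load crosses a threshold and the naive
      population crashes;
    - variants pre-exist at ``variant_fraction`` of the inoculum and emerge
      from naive hosts at rate ``emergence``; they repopulate the culture
      after the crash while still carrying the parasite, giving a single
      crash/recovery episode and a persistent parasite score;
    - ``attachment = 0`` (resistant host) leaves the load to wash out, and
      ``damage = 0`` (nonpermissive host) leaves density tracking the
      uninfected control.

    Densities are in units of the carrying capacity; the parasite score is
    the saturating transform ``lam / (lam + score_half)``.
    """

    phenotype: str = PERMISSIVE
    growth_rate: float = 0.2  # host logistic rate, /h
    carrying_capacity: float = 1.0
    attachment: float = 1.0  # 0 for hosts the parasite cannot colonize
    replication: float = 0.22  # parasite replication on attached hosts, /h
    damage: float = 1.0  # naive death coefficient, /h at unit per-host load
    damage_exponent: float = 4.0  # cooperativity of killing in per-host load
    kill_cap: float = 4.0  # max naive death rate, /h
    emergence: float = 1e-5  # naive -> resistant-variant conversion, /h
    variant_fraction: float = 1e-3  # standing resistant variants in inoculum
    decay: float = 0.05  # parasite decay, /h
    load_capacity: float = 20.0  # max per-host parasite load
    score_half: float = 1.0  # per-host load giving score 0.5
    dose: float = 3.0  # initial parasite-to-host cell ratio (study default 3:1)
    n_passages: int = 12
    dilution: float = 0.1  # 1:10 into fresh medium every 24 h
    inoculum: float = 0.1  # starting host density
    od_noise: float = 0.02  # shared plate-reading noise (lognormal sd)
    score_noise: float = 0.02
    growth_jitter: float = 0.05  # per-passage lognormal sd on parasite growth
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("growth_rate", "attachment", "replication", "damage", "emergence",
                     "decay", "dose", "load_capacity", "damage_exponent", "kill_cap",
                     "variant_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.dilution < 1:
            raise ValueError("dilution must lie in (0, 1)")
        if self.n_passages < 3:
            raise ValueError("need at least 3 passages")


#: phenotype presets: resistant hosts force attachment to 0 (the load can
#: only decay); nonpermissive hosts force damage to 0 (the load rides along
#: without crashing the culture); permissive hosts use the config values.
PHENOTYPE_PARAMS: dict[str, dict[str, float]] = {
    RESISTANT: {"attachment": 0.0, "damage": 0.0},
    NONPERMISSIVE: {"damage": 0.0},
    PERMISSIVE: {},
}


def simulate_passages(cfg: PassageSimConfig, strain: str = "sim") -> PassageSeries:
    """Run the passage model; returns a :class:`PassageSeries` with control.

    Phenotype presets override ``attachment``/``damage`` according to
    ``cfg.phenotype``. Deterministic for a fixed config (the seed drives
    all noise).
    """
    if cfg.phenotype not in PHENOTYPE_PARAMS:
        raise ValueError(f"unknown phenotype {cfg.phenotype!r}")
    alpha = 0.0 if cfg.phenotype == RESISTANT else cfg.attachment
    delta = cfg.damage if cfg.phenotype == PERMISSIVE else 0.0
    rng = np.random.default_rng(cfg.seed)
    K = cfg.carrying_capacity
    hn = cfg.inoculum * (1.0 - cfg.variant_fraction)
    hr = cfg.inoculum * cfg.variant_fraction
    ctrl = cfg.inoculum
    lam = cfg.dose  # per-host parasite load; dilution leaves it unchanged

    passages, density, control, score, total_cfu, irregular_cfu = [], [], [], [], [], []
    for p in range(cfg.n_passages + 1):
        rho = cfg.replication * float(rng.lognormal(0.0, cfg.growth_jitter))
        for _ in range(24):  # hourly exponential-Euler steps across one passage
            h = hn + hr
            g = cfg.growth_rate * (1.0 - h / K)
            kill = min(delta * lam**cfg.damage_exponent, cfg.kill_cap)
            grown_hn = hn * math.exp(g - kill)
            grown_hr = hr * math.exp(g)
            converted = grown_hn * -math.expm1(-cfg.emergence)  # mass-conserving
            hn = grown_hn - converted
            hr = grown_hr + converted
            lam *= math.exp(rho * alpha * (1.0 - lam / cfg.load_capacity) - cfg.decay - g)
            ctrl *= math.exp(cfg.growth_rate * (1.0 - ctrl / K))
            if not all(math.isfinite(x) for x in (hn, hr, lam, ctrl)):
                raise ArithmeticError(f"non-finite state at passage {p}")

        od_factor = float(rng.lognormal(0.0, cfg.od_noise))  # shared plate reading
        h = hn + hr
        if cfg.dose > 0:
            s = lam / (lam + cfg.score_half)
            s = float(np.clip(s + rng.normal(0.0, cfg.score_noise), 0.0, 1.0))
        else:
            s = 0.0
        passages.append(p)
        # without parasite the coculture IS the control culture
        density.append((h if cfg.dose > 0 else ctrl) * od_factor)
        control.append(ctrl * od_factor)
        score.append(s)
        total_cfu.append(h * 1e8)
        irregular_cfu.append(min(lam, 1.0) * hn * 1e8)

        hn *= cfg.dilution
        hr *= cfg.dilution
        ctrl *= cfg.dilution

    return PassageSeries(
        strain=strain,
        dose=cfg.dose,
        passage=np.array(passages),
        density=np.array(density),
        parasite_score=np.array(score),
        control_density=np.array(control),
        total_cfu=np.array(total_cfu),
        irregular_cfu=np.array(irregular_cfu),
    )
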