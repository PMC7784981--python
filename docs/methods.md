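# Methods

This note records the models, statistics and design choices behind
`epirange`, and what the synthetic-data generators do and do not emulate.

## Pangenome set algebra

The central object is a genomes × gene-clusters copy-number matrix
(`GeneClusterMatrix`). A gene cluster is an operationally defined group of
putatively homologous genes; the matrix is consumed, not built — gene
calling, all-vs-all similarity search and clustering are upstream of this
package.

Presence is defined as copy count ≥ 1. Multi-copy information is retained
in the counts but collapsed to presence/absence for the set operations,
matching how pangenomes are usually displayed and reasoned about; the full
counts are still needed for the single-copy filter.

- `core_clusters(m, S)`: present in **every** genome of S (strict;
  draft-genome incompleteness can deflate cores, so a relaxation threshold
  would be a natural extension, but strict presence-in-all is the default
  and only shipped behavior).
- `exclusive_core(m, in, out)`: present in every in-group genome and
  absent from every out-group genome.
- `single_copy_core(m, S)`: exactly one copy in every genome of S. These
  clusters have one sequence per genome and are the admissible inputs for
  per-cluster gene trees.

Loading sorts genomes and clusters lexicographically, making the matrix
independent of input row order.

## Functional enrichment

Each annotated function is collapsed to a per-genome presence bit (a
genome has the function iff ≥ 1 cluster annotated with it is present), and
tested for association with the phenotype grouping.

**Statistic.** The Rao (efficient) score test of a binary outcome against
a categorical predictor, which equals the Pearson chi-square on the
2 × G (present/absent × group) table:

S = Σ_g (k_g − n_g p̂)² / (n_g p̂ (1 − p̂)),  p̂ = Σ_g k_g / Σ_g n_g.

Both cells of a column share the same squared residual, giving the reduced
form above. S = 0 when the function is present in all or no genomes
(defined, not an error), and S attains its maximum N (the number of
labeled genomes) exactly when presence coincides with a nonempty proper
union of whole groups — so perfect group markers in a 10/3/10 design score
23.

**Choices.**

- Degrees of freedom are always G − 1 with G = 3 groups, even for
  functions whose carriers span a combined grouping (e.g. nonpermissive +
  resistant): the grouping is not re-merged per function.
- No continuity correction and no minimum-expected-count rule. Expected
  counts in a group of 3 are small; the uncorrected statistic is the
  deliberate convention here (and what reproduces the published scores the
  test suite pins).
- p-values are the χ²(G−1) upper tail; q-values are Benjamini–Hochberg
  over **all tested functions** (the full annotated universe, not a
  filtered subset). q-values therefore depend on the universe size, while
  scores do not. Only annotated functions enter the universe.
- Functions are keyed by accession by default (`annotation_source=
  "annotation"` switches to annotation text).
- Associated groups: every group with presence fraction ≥ 0.5 (majority
  rule, inclusive at the boundary so a 5/10 group qualifies). Alternatives
  (e.g. fraction above the cross-group mean) were considered and not
  implemented.
- Ranking: descending score, ties broken lexicographically by accession.

## Gene-tree topology screening

Trees are screened for topologies in which sequence variants separate the
phenotype groups. Three constraints ship:

- `ALL_MONO` (three-group trees): resistant, nonpermissive and permissive
  leaf sets each monophyletic;
- `R_SISTER_NP`: as above, and resistant ∪ nonpermissive also a clade
  (resistant sister to nonpermissive);
- `P_NP_SPLIT` (two-group trees over the susceptible genomes): permissive
  vs nonpermissive leaves separable by a single branch.

**Polytomy semantics.** A polytomy is treated as unresolved signal, not as
evidence against a clade: a tree matches a constraint iff *some* binary
resolution of its polytomies satisfies it. Split compatibility is decided
by the minimal-subtree characterization — the split A | B can be displayed
by a refinement iff the minimal subtree connecting A and the minimal
subtree connecting B share at most one vertex. Rooted clade compatibility
holds iff every child subtree of the MRCA of the group is entirely inside
or outside the group. For a laminar family of groups (disjoint groups,
plus unions of groups), per-set compatibility implies a single joint
resolution exists, since each set claims a disjoint subset of children at
its MRCA polytomy; the test suite verifies this against exhaustive
enumeration of binary resolutions on trees with ≤ 8 leaves. A star tree
consequently matches every applicable constraint; the screen reports the
number of internal edges per tree so trivially under-resolved matches can
be filtered downstream.

**Rooting.** With all three groups monophyletic, an unrooted tree cannot
distinguish `ALL_MONO` from `R_SISTER_NP` (contracting each clan leaves a
3-leaf star), so the rooted constraints are evaluated on the tree in its
as-parsed orientation by default, with midpoint and explicit-outgroup
rooting available. The choice is exposed rather than guessed because tree
files produced by fast ML programs record an arbitrary but stable
orientation.

**Classification** is exclusive and most-specific-first: a three-group
tree is reported under `R_SISTER_NP` if it matches, else `ALL_MONO`, else
none. Branch lengths and support values are parsed and ignored. When a
gene-cluster matrix is supplied, trees whose cluster is not single-copy
across their leaf genomes are logged and skipped.

## Growth phenotyping

The classifier formalizes what is usually read off growth curves by eye.
All density comparisons are control-relative (infected / host-alone ratio),
which removes strain- and medium-specific growth-rate confounds and makes
the calls invariant to uniform rescaling of both series.

- **Crash point**: first passage with ratio < `drop_fraction`
  (default 0.5).
- **Crash duration**: consecutive passages (from the crash point) with
  ratio < `recovery_fraction` (default 0.8).
- **Call**: *resistant* if the parasite score stays below
  `establish_score` (default 0.1) at every passage ≥ `establish_passages`
  (default 5, matching the usual 5–8-passage establishment window);
  otherwise *permissive* if a crash is found, else *nonpermissive*.
  Resistance is judged on the parasite score only — density plays no role,
  because a resistant host's density never deviates from control anyway.
- **Dose response**: crash points must be non-increasing in parasite dose
  (no crash counts as +∞); violating pairs are reported, and duplicate
  doses with conflicting crash points are flagged but not fatal.

The 0.5/0.8 thresholds are conventions, exposed as options: published
crash identification is visual, and cfu-based crash points are known to
lead OD-based ones by ~1–1.5 passages, so no threshold is canonical.
Optional cfu columns are carried through but never change the call.

## Synthetic data

### Pangenome generator

Defaults emulate the 23-genome study design: groups of 10 resistant /
3 nonpermissive / 10 permissive genomes; 346 core clusters (15% of which
carry a paralog in one random genome, so the single-copy core is a strict
subset); 464 susceptible-, 51 resistant-, 28 nonpermissive-exclusive
clusters; and 11,443 background clusters present independently with
probability θ = 0.15, which puts every genome's repertoire in the
~1700–2800 band and the total at 12,372 clusters. The
permissive-exclusive count is not a published number; 40 was chosen once
as the same order as the printed nonpermissive/resistant counts. Every
planted cluster carries one unique function accession; background clusters
are annotated too (they form the null part of the testing universe).

The generator plants *exact* group patterns: it emulates the presence/
absence structure of a real pangenome, not sequence evolution, annotation
noise, assembly incompleteness or correlated gene gain/loss. Passing
recovery tests therefore shows the statistics behave correctly on clean
group signal over independent noise — not that real pangenomes are this
clean.

### Gene-tree generator

Concordant trees join random within-group subtrees under the phenotype
nesting ((resistant, nonpermissive), permissive) — or (permissive,
nonpermissive) for two-group leaf sets; discordant trees join all leaves
in random order. `resolution_prob` is the probability each internal edge
is kept (1 → fully binary); contraction only removes resolution, so a
concordant tree remains constraint-compatible after polytomy
introduction. Branch lengths are exponential (mean 0.05) and ignored by
the screen. Random joins can match a constraint by chance on small leaf
sets; tests cross-check such matches against the enumeration oracle
rather than assuming zero.

### Passage simulator

A deliberately minimal discrete-passage consumer–resource sketch, chosen
for qualitative fidelity (single crash, dose-shifted crash point,
recovery via resistant-variant takeover) and not fit to any real curves.
State per culture: naive hosts, resistant-variant hosts (densities in
units of carrying capacity) and the per-host parasite load λ; a matching
host-alone control runs alongside. Each 24 h passage integrates hourly
multiplicative (exponential-Euler) steps — stable and positivity-
preserving — followed by a 1:10 dilution:

- hosts grow logistically at rate r = 0.2 /h toward capacity;
- the per-host load multiplies by exp(ρ·α·(1 − λ/κ) − d − g): replication
  ρ = 0.22 /h on attached hosts, capped at κ = 20 parasites per host,
  decay d = 0.05 /h, and dilution by host division at the current logistic
  rate g (attached epibionts ride their dividing hosts, so the 1:10
  passage dilution leaves λ unchanged);
- naive hosts die at min(δ·λ⁴, 4) /h with δ = 1.0. The quartic makes
  killing cooperative — a host with several attached parasites dies, one
  with few does not — so the death rate switches on sharply near λ ≈ 1.
  A linear death term was tried first and produces a stable host/parasite
  coexistence (a slow bleed rather than a crash), which is not the
  phenomenology being emulated;
- variants pre-exist at 10⁻³ of the inoculum and emerge from naive hosts
  at 10⁻⁵ /h; they resist killing but still carry the parasite, so after
  a crash the culture recovers while the parasite score stays high —
  exactly one crash/recovery episode;
- phenotype presets: resistant forces attachment α = 0 (the load washes
  out), nonpermissive forces δ = 0 (full load, no crash), permissive uses
  both defaults.

Observables: density = total host density with a per-passage lognormal
plate-reading factor (σ = 0.02) shared between coculture and control (so
dose 0 reproduces the control series exactly and ratios are noise-free);
parasite score = λ/(λ+1) plus N(0, 0.02) clipped to [0, 1]; cfu analogs
derived from density and load. The only process noise is a per-passage
lognormal jitter (σ = 0.05) on the replication rate.

With λ growing ≈ ×4 per passage, the default dose grid 0.01–100 (five
doses spanning four orders of magnitude, bracketing the study's 3:1
standard inoculum) yields crash points spread over passages 0–3 within the
12-passage window, monotone in dose.

## Problem sizes and numerical conventions

- Oracle batteries: set algebra on 1000 random matrices (≤ 7 genomes ×
  ≤ 14 clusters, counts 0–3); topology checks on > 500 random
  (tree, subset) instances with ≤ 8 leaves against full resolution
  enumeration; chi-square against an explicit observed/expected loop on
  1200 random tables.
- Power/FDR: planted recovery at the default study-scale configuration
  (3 replicates, ~1750 planted functions); null calibration on 200
  pangenomes of 400 background clusters with no group structure, FDR
  compared against 0.05 + 3 binomial standard errors.
- Phenotype grid: 3 phenotypes × 5 doses × 20 seeds (300 simulations).
- Scores are exact rational arithmetic in floating point — no tolerance
  tricks; published-score tests assert to the printed precision (±0.005).
- Ties in enrichment ranking break lexicographically; set outputs are
  sorted; all generators are pure functions of (config, seed) using
  numpy's `default_rng`.

## Limitations

- The enrichment test is a per-function marginal screen: no phylogenetic
  correction, so lineage-confounded functions score high (the topology
  screen is the complementary, tree-aware view).
- q-values depend on the tested-function universe; comparing q-values
  across datasets with different universes is not meaningful.
- The topology screen's rooted constraints depend on the chosen rooting;
  the default trusts the as-parsed orientation.
- Star trees match everything by construction; filter on
  `n_internal_edges` when that is not wanted.
- The passage model is a caricature with hand-set rates; it supports
  testing the classifier, not inference about real kinetics.
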