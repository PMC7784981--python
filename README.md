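# epirange

Comparative-genomics toolkit for bacterial epibiont host-range studies.

Ultrasmall epibiotic parasites (e.g. oral Saccharibacteria growing on
*Actinomyces* hosts) split their candidate hosts into phenotype groups:
**resistant** strains never carry the parasite, **permissive** strains crash
and recover after infection, and **nonpermissive** strains carry it without
a growth crash. `epirange` implements the downstream comparative analysis
that connects those phenotypes to genome content:

- **pangenome set algebra** — core, group-exclusive-core and
  single-copy-core gene-cluster sets from a genomes × gene-clusters
  copy-number matrix (`epirange.pangenome`);
- **functional enrichment** — for each annotated function, a Rao score
  statistic of association between function presence and phenotype group.
  For a binary outcome and a categorical predictor this is the Pearson
  chi-square on the 2 × G contingency table,

  ```
  S = Σ_g (k_g − n_g p̂)² / (n_g p̂ (1 − p̂)),   p̂ = Σ k_g / Σ n_g
  ```

  with k_g of n_g genomes in group g carrying the function; p-values from
  χ²(G−1), q-values by Benjamini–Hochberg over all tested functions, and an
  associated-group call by ≥ 0.5 majority rule (`epirange.enrichment`);
- **gene-tree topology screening** — single-copy core gene trees are
  screened for topologies separating the phenotype groups, with polytomies
  read permissively: a tree matches if *some* resolution of its polytomies
  displays the required clades or split (`epirange.trees`);
- **growth phenotyping** — resistant / permissive / nonpermissive calls
  from serial-passage OD + parasite-score series, with a control-relative
  crash point and crash duration, and a dose–response monotonicity report
  (`epirange.growth`);
- **synthetic data** — truth-known generators for group-structured
  pangenomes, concordant/discordant gene trees, and dose-dependent
  crash/recovery passage dynamics (`epirange.simulate`).

## Worked example

Generate a synthetic study (23 genomes: 10 resistant / 3 nonpermissive /
10 permissive; 12,372 gene clusters with planted core and group-exclusive
sets; 20 gene trees; passage curves at five doses), then run the stages:

```bash
epirange simulate --seed 1 --out-dir demo --n-trees 20
epirange core-sets --table demo/gene_clusters.tsv --phenotypes demo/phenotypes.tsv --out-dir demo/sets
```

prints the recovered set sizes:

```
core_all                      346
exclusive_nonpermissive       28
exclusive_permissive          40
exclusive_resistant           51
exclusive_susceptible         464
single_copy_core_all          294
single_copy_core_susceptible  777
```

The planted design (346 core, 464/51/28/40 exclusive) is recovered exactly
at this seed; with other seeds a background cluster occasionally lands on a
group pattern by chance (~11,400 background clusters at 15% presence yield
about one such coincidence per run). `core_all` exceeds
`single_copy_core_all` because a planted fraction of core clusters carries
a paralog in one genome.

```bash
epirange enrich --table demo/gene_clusters.tsv --phenotypes demo/phenotypes.tsv --out demo/enrich.tsv --top-n 5
```

Top rows of `demo/enrich.tsv` (a function present in all 3 nonpermissive
genomes and absent elsewhere is a perfect group marker, scoring N = 23 with
p = exp(−11.5) ≈ 1.01e−5):

```
accession  enrichment_score  p_value    q_value    observation_resistant  observation_nonpermissive  observation_permissive  associated_groups
FXN00000   23.0              1.013e-05  2.150e-04  0/10                   3/3                        0/10                    nonpermissive
```

```bash
epirange screen --trees-dir demo/trees --phenotypes demo/phenotypes.tsv --out demo/screen.tsv
# R_SISTER_NP  9     <- planted concordant trees: groups monophyletic,
# ALL_MONO     0        resistant sister to nonpermissive
# P_NP_SPLIT   0
# none         11    <- random trees
epirange phenotype --passages demo/passages.csv --out demo/calls.tsv
# sim_permissive  dose-monotone=True  violations=0
```

The phenotype stage calls each (strain, dose) series and confirms that
crash points move earlier as parasite dose increases.

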