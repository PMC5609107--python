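# genospecies

Delineation of bacterial genospecies from whole-genome data, as a single
tested pipeline:

* **fragsim** — Gegenees-style fragmented all-vs-all genome similarity
  (200 bp windows, 100 bp step), with a symmetric distance matrix exported as
  a SplitsTree-compatible nexus `DISTANCES` block;
* **ani** — fragment-based average nucleotide identity (1,020 bp pieces,
  70 % identity / 70 % coverage retention, direction-averaged) and
  single-linkage clustering at a cutoff (default 94 %) into clusters and
  singleton strains;
* **wgmlst** — a pan-locus allele database built greedily at 90 % identity /
  80 % coverage, allele-profile calling, profile distances and a UPGMA
  dendrogram;
* **pangenome** — ortholog families from an all-vs-all protein similarity
  graph clustered with an in-house Markov Cluster (MCL) implementation,
  partitioned into core / shell / singleton subsets;
* **heaps** — permutation-based pangenome/core/new-gene development curves,
  a Heap's-law fit (α = 1 − γ, α ≤ 1 ⇒ open pangenome) and an exponential
  decay fit `n(x) = k·exp(−x/t) + tg(θ)` whose asymptote is the converged
  core size, culminating in a joint **ANI + α species-support verdict** per
  cluster (a cluster is supported when its α exceeds the whole-cohort α by a
  margin and all intra-cluster ANI values reach the cutoff);
* **marker_phylo** — Kimura 2-parameter distances on aligned marker genes
  (matrix-wide complete deletion) and a neighbor-joining tree;
* **simulate** — a synthetic-cohort generator with known cluster structure
  (shared core, cluster-specific accessory genes, strain-private singletons,
  tunable within/between divergence) providing ground truth for every stage;
* **align** — the shared local-alignment engine: exact Smith–Waterman
  (affine gaps) for short inputs, k-mer seeded exact gapless diagonal
  extension for genome-scale subjects, both strands searched.

A 17-strain cohort table and its 17×17 ANI matrix are packaged as printed
fixtures (`src/genospecies/data/`) and drive the desk-scale checks.

## CLI

```sh
genospecies simulate --out cohort/ --seed 1
genospecies ani --genomes cohort/ --cutoff 94
genospecies cluster --matrix ani_matrix.tsv --cutoff 94
genospecies wgmlst --genes cohort/genes/
genospecies pangenome --proteins cohort/proteins/
genospecies heaps --presence pangenome_presence.tsv \
    --clusters ani_clusters.json --ani-matrix ani_matrix.tsv
genospecies phylo --aligned markers.afa
genospecies run --seed 1 --out out/        # full pipeline on a simulated cohort
genospecies demo                           # stages computable from the printed tables
```

`run` writes per-stage artifacts (TSV/JSON/newick/nexus), a sha256 manifest
and a machine-readable `report.json`; identical config + seed reproduce
byte-identical artifacts.

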