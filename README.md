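# adjbin — taxonomic binning of discarded metagenomic fragments via conserved gene adjacency

Homology-based taxonomic binning of Sanger-scale shotgun metagenomes
discards 30–40% of fragments: reads whose BLASTX hits are individually too
weak to pass the usual score cut-offs.  Many of those reads, at ~1 kb,
still span **two or more partial coding regions**.  `adjbin` implements a
binning criterion that rescues them: instead of trusting a single strong
hit, it asks whether a read's hit genes are **directly adjacent** in a
reference genome with the **same transcriptional arrangement** the read
shows.  Local gene order is strongly conserved within prokaryotic lineages
and shuffled between distant ones, so a conserved adjacent pair is
taxonomically informative even when each hit alone is marginal.

It is aimed at people benchmarking or re-analysing fragment-level
taxonomic binning — anyone with reference gene annotations, a taxonomy and
tabular BLASTX output, no aligner run required.

## Method

For each read *q* with tabular translated-search hits:

1. **Filter** — keep hits with *E* ≤ 10⁻⁵, then the top 250 by bit score
   (both configurable; ties broken by *E*-value, then subject id).
2. **Locus calling** — single-linkage clustering of hit intervals on the
   read (same read strand, overlap > 50% of the shorter interval) yields
   the read's candidate CDS loci; a read needs ≥ 2 loci to proceed.
3. **Adjacency test** — hits are grouped per reference taxon; every hit
   pair from distinct loci is looked up in the reference adjacency index
   (genes at consecutive positions on one replicon; the wrap-around pair
   on circular replicons).  A pair is *consistent* when the read-side
   arrangement (locus order + strands) equals the genomic arrangement
   (gene order + strands) of the reference — for the read as-is or its
   reverse complement.  Each adjacent pair carries one of the three
   transcriptional direction classes: unidirectional (→→), convergent
   (→←), divergent (←→).  Inconsistent pairs are removed.
4. **Assignment** — the read is assigned to the **lowest common ancestor**
   (LCA) of all taxa supported by a consistent pair; with no consistent
   pair it is *unclassified*.

Accuracy per taxonomic class *i* at a rank follows the adapted
sensitivity/specificity convention for binning benchmarks:

    Sn_i = TP_i / (TP_i + FN_i + U_i)        Sp_i = TP_i / (TP_i + FP_i)

with *U_i* counting class-*i* fragments left unclassified or assigned
above the rank.  Composition profiles of two binnings are compared by the
Pearson correlation of per-phylotype counts after phylotypes with fewer
than five fragments in both profiles are pooled into a shared "other"
category.

The package also ships a seeded synthetic-community generator (genomes at
the canonical prokaryotic density of one gene per ~1,000 nt, ~1 kb reads,
true/homolog/spurious hits) so the whole pipeline and its criteria grid
(*E* ∈ {10⁻², 10⁻⁴, 10⁻⁶} × top-N ∈ {50, 150, 250, 350}, with and without
the adjacency criterion) can be benchmarked without downloading anything.

## Worked example

```python
from adjbin import (SimConfig, simulate_community, build_adjacency_index,
                    bin_dataset, accuracy_table, macro_average, recovery_rate)

community = simulate_community(SimConfig(n_reads=1000, seed=42))
index = build_adjacency_index(community.catalog)
assignments = bin_dataset(community.hit_table, index,
                          community.catalog, community.tree)
n = sum(a.assigned for a in assignments)
print(f"assigned {n}/{len(community.reads)} reads "
      f"(recovery rate {recovery_rate(n, len(community.reads))}%)")
table = accuracy_table(assignments, community.truth, community.tree)
for rank in ("phylum", "order", "family", "genus"):
    avg = macro_average(table, rank)
    print(f"{rank:>7}: Sn {100*avg['sn']:.1f}%  Sp {100*avg['sp']:.1f}%")
```

prints

```
assigned 526/1000 reads (recovery rate 52.6%)
 phylum: Sn 52.7%  Sp 100.0%
  order: Sn 52.7%  Sp 100.0%
 family: Sn 52.8%  Sp 100.0%
  genus: Sn 52.9%  Sp 100.0%
```

About half of the synthetic ~1 kb reads carry a detectable adjacent gene
pair; essentially all of those are recovered, and every assignment sits on
the true lineage (macro specificity 100% here — the homolog and spurious
noise in this community misleads the plain best-hit LCA, not the
adjacency test).  The same pipeline is available from the shell:

```sh
adjbin simulate --config config.json --out-dir sim/
adjbin index --annotations sim/annotations.tsv --format tsv --out index.json
adjbin assign --hits sim/hits.tsv --gene-map sim/gene_map.tsv \
              --index index.json --nodes sim/taxonomy.tsv --out assignments.tsv
adjbin evaluate --assignments assignments.tsv --truth sim/truth.tsv \
                --nodes sim/taxonomy.tsv
```

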