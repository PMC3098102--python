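"""Synthetic communities, reads and hit tables with truth labels.

The generator emulates the setting the method targets: prokaryotic genomes
at the canonical density of about one gene per 1,000 nt (default 950 nt
genes, 50 nt intergenic gaps), sampled by ~1 kb shotgun fragments whose
translated-search hits land in a 12-column tabular hit file.  Three kinds
of hits are produced:

* *true* hits to every reference gene the read genuinely overlaps by at
  least ``min_hit_overlap`` nt (detectability floor of a translated hit),
* *homolog* hits mirroring a read's true hits into sister species of the
  same genus — gene order and strand layout are shared within a genus,
  emulating gene-order conservation between close relatives,
* *spurious* hits to random genes anywhere, at weak E-values.

Everything is deterministic for a fixed seed.  An aligner is never run:
the binning logic consumes only the tabular fields, so E-values, bit
scores and identities are drawn from configured distributions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adjacency_binning import (
    BinningCriteria,
    bin_dataset,
    bin_dataset_plain_lca,
)
from .errors import ValidationError
from .evaluation import accuracy_table, macro_average
from .hit_processing import BlastHit, HitTable
from .reference_index import (
    FORWARD,
    REVERSE,
    GeneCatalog,
    GeneRecord,
    RepliconMeta,
    build_adjacency_index,
)
from .taxonomy import NO_RANK, TaxNode, TaxonomyTree


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic community generator (lengths in nt)."""

    n_genomes: int = 24
    genes_per_genome: int = 40
    mean_gene_length: int = 950
    gene_length_sd: float = 150.0
    mean_gap: int = 50
    gap_sd: float = 15.0
    min_gene_length: int = 100
    strand_flip_p: float = 0.25
    topology: str = "circular"
    read_length: int = 1000
    n_reads: int = 2000
    # taxonomy branching, bottom-up
    species_per_genus: int = 2
    genera_per_family: int = 2
    families_per_order: int = 2
    orders_per_class: int = 1
    classes_per_phylum: int = 1
    # hit model
    min_hit_overlap: int = 200
    min_gene_overlap: int = 1
    homolog_hit_p: float = 0.3
    true_e_range: tuple = (1e-40, 1e-10)
    homolog_e_range: tuple = (1e-18, 1e-8)
    spurious_e_range: tuple = (1e-8, 1e-2)
    spurious_rate: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class SimRead:
    """One simulated shotgun fragment with its truth label."""

    read_id: str
    genome_id: str
    replicon_id: str
    start: int  # 1-based on the replicon; wraps on circular replicons
    length: int
    strand: str
    overlapped_gene_ids: tuple
    truth_taxon: int


@dataclass
class SimCommunity:
    """A complete synthetic instance: references, taxonomy, reads, hits, truth."""

    config: SimConfig
    catalog: GeneCatalog
    tree: TaxonomyTree
    reads: list[SimRead] = field(default_factory=list)
    hit_table: HitTable = field(default_factory=HitTable)

    @property
    def truth(self) -> dict[str, int]:
        return {r.read_id: r.truth_taxon for r in self.reads}

    def gene_map(self) -> dict[str, tuple[str, int]]:
        """subject_id -> (gene_id, taxon_id) for every reference protein."""
        return {f"p_{g.gene_id}": (g.gene_id, g.taxon_id) for g in self.catalog.genes}


# ---------------------------------------------------------------------------
# Taxonomy and genome layout
# ---------------------------------------------------------------------------

def _rank_divisors(cfg: SimConfig) -> dict[str, int]:
    genus = cfg.species_per_genus
    family = genus * cfg.genera_per_family
    order = family * cfg.families_per_order
    klass = order * cfg.orders_per_class
    phylum = klass * cfg.classes_per_phylum
    return {"genus": genus, "family": family, "order": order, "class": klass, "phylum": phylum}


def _build_taxonomy(cfg: SimConfig) -> tuple[TaxonomyTree, list[int]]:
    nodes = {
        1: TaxNode(1, 1, NO_RANK, "root"),
        2: TaxNode(2, 1, "superkingdom", "Bacteria"),
    }
    divisors = _rank_divisors(cfg)
    next_id = 3
    cache: dict[tuple[str, int], int] = {}
    species_ids: list[int] = []
    for i in range(cfg.n_genomes):
        parent = 2
        for rank in ("phylum", "class", "order", "family", "genus"):
            grp = i // divisors[rank]
            key = (rank, grp)
            if key not in cache:
                cache[key] = next_id
                nodes[next_id] = TaxNode(next_id, parent, rank, f"{rank}_{grp}")
                next_id += 1
            parent = cache[key]
        nodes[next_id] = TaxNode(next_id, parent, "species", f"species_{i}")
        species_ids.append(next_id)
        next_id += 1
    return TaxonomyTree(nodes=nodes), species_ids


def _sample_lengths(rng, mean: int, sd: float, minimum: int, n: int) -> np.ndarray:
    if sd <= 0:
        return np.full(n, mean, dtype=int)
    vals = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.maximum(vals, minimum)


def _layout_genomes(cfg: SimConfig, rng, species_ids: list[int]) -> GeneCatalog:
    genes: list[GeneRecord] = []
    topologies: dict[str, str] = {}
    lengths: dict[str, int] = {}
    genus_div = cfg.species_per_genus
    # strand pattern shared within a genus (gene-order/strand conservation
    # between close relatives); sampled as runs of co-oriented genes
    genus_strands: dict[int, list[str]] = {}
    for i in range(cfg.n_genomes):
        genus = i // genus_div
        if genus not in genus_strands:
            strands = []
            cur = FORWARD
            for _ in range(cfg.genes_per_genome):
                if rng.random() < cfg.strand_flip_p:
                    cur = REVERSE if cur == FORWARD else FORWARD
                strands.append(cur)
            genus_strands[genus] = strands
        strands = genus_strands[genus]
        genome_id = f"G{i:02d}"
        rep_id = f"{genome_id}_chr"
        gl = _sample_lengths(
            rng, cfg.mean_gene_length, cfg.gene_length_sd, cfg.min_gene_length,
            cfg.genes_per_genome,
        )
        gaps = _sample_lengths(rng, cfg.mean_gap, cfg.gap_sd, 1, cfg.genes_per_genome)
        pos = 1
        for j in range(cfg.genes_per_genome):
            start, end = pos, pos + int(gl[j]) - 1
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=rep_id,
                    taxon_id=species_ids[i],
                    gene_id=f"{genome_id}_g{j:03d}",
                    start=start,
                    end=end,
                    strand=strands[j],
                    order_rank=j,
                )
            )
            pos = end + int(gaps[j]) + 1
        rep_len = pos - 1  # trailing gap doubles as the wrap gap when circular
        if cfg.read_length > rep_len:
            raise ValidationError(
                f"infeasible geometry: read length {cfg.read_length} exceeds "
                f"replicon length {rep_len}"
            )
        topologies[rep_id] = cfg.topology
        lengths[rep_id] = rep_len
    replicons = {
        rid: RepliconMeta(replicon_id=rid, length=lengths[rid], topology=topologies[rid])
        for rid in lengths
    }
    genome_taxon = {f"G{i:02d}": species_ids[i] for i in range(cfg.n_genomes)}
    return GeneCatalog(genes=genes, replicons=replicons, genome_taxon=genome_taxon)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def _read_segments(start: int, length: int, rep_len: int) -> list[tuple[int, int]]:
    """A read as 1-based genomic segments, split at the circular origin."""
    end = start + length - 1
    if end <= rep_len:
        return [(start, end)]
    return [(start, rep_len), (1, end - rep_len)]


def _gene_read_overlap(
    gene: GeneRecord, segments: list[tuple[int, int]]
) -> Optional[tuple[int, int]]:
    """The genomic interval where a gene intersects a read, or None."""
    for a, b in segments:
        lo, hi = max(gene.start, a), min(gene.end, b)
        if lo <= hi:
            return lo, hi
    return None


def _sample_reads(cfg: SimConfig, rng, catalog: GeneCatalog) -> list[SimRead]:
    reads: list[SimRead] = []
    genome_ids = sorted(catalog.genome_taxon)
    for k in range(cfg.n_reads):
        genome_id = genome_ids[int(rng.integers(0, len(genome_ids)))]
        rep_id = f"{genome_id}_chr"
        meta = catalog.replicons[rep_id]
        if meta.topology == "circular":
            start = int(rng.integers(1, meta.length + 1))
        else:
            start = int(rng.integers(1, meta.length - cfg.read_length + 2))
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        segments = _read_segments(start, cfg.read_length, meta.length)
        overlapped = tuple(
            g.gene_id
            for g in catalog.genes_on(rep_id)
            if (ov := _gene_read_overlap(g, segments)) is not None
            and ov[1] - ov[0] + 1 >= cfg.min_gene_overlap
        )
        reads.append(
            SimRead(
                read_id=f"read_{k:06d}",
                genome_id=genome_id,
                replicon_id=rep_id,
                start=start,
                length=cfg.read_length,
                strand=strand,
                overlapped_gene_ids=overlapped,
                truth_taxon=catalog.genome_taxon[genome_id],
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Hit-table simulation
# ---------------------------------------------------------------------------

def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _query_interval(
    genome_lo: int, genome_hi: int, read: SimRead, rep_len: int
) -> tuple[int, int]:
    """Map a genomic interval inside the read to 1-based read coordinates."""
    off_lo = (genome_lo - read.start) % rep_len + 1
    off_hi = (genome_hi - read.start) % rep_len + 1
    if read.strand == FORWARD:
        return off_lo, off_hi
    return read.length - off_hi + 1, read.length - off_lo + 1


def _hit_is_forward(gene_strand: str, read_strand: str) -> bool:
    return gene_strand == read_strand


def simulate_hit_table(community: SimCommunity, config: SimConfig) -> HitTable:
    """Generate the tabular hit set for every read of a community.

    Deterministic for a fixed config seed (an independent stream from the
    one used for genome layout and read sampling).
    """
    rng = np.random.default_rng(config.seed + 1)
    catalog = community.catalog
    hits: list[BlastHit] = []
    genome_ids = sorted(catalog.genome_taxon)
    genus_of = {gid: i // config.species_per_genus for i, gid in enumerate(genome_ids)}
    genus_members: dict[int, list[str]] = {}
    for gid, genus in genus_of.items():
        genus_members.setdefault(genus, []).append(gid)
    all_genes = sorted(catalog.genes, key=lambda g: g.gene_id)

    def emit(read: SimRead, gene: GeneRecord, q_lo: int, q_hi: int, forward: bool,
             e_range: tuple, bits_per_nt: float, pid_range: tuple) -> None:
        overlap = q_hi - q_lo + 1
        evalue = _log_uniform(rng, *e_range)
        bit = round(bits_per_nt * overlap + rng.uniform(-5, 5), 1)
        pident = round(rng.uniform(*pid_range), 1)
        q_start, q_end = (q_lo, q_hi) if forward else (q_hi, q_lo)
        aa = max(1, overlap // 3)
        hits.append(
            BlastHit(
                query_id=read.read_id,
                subject_id=f"p_{gene.gene_id}",
                percent_identity=pident,
                align_length=aa,
                evalue=evalue,
                bit_score=max(bit, 25.0),
                q_start=q_start,
                q_end=q_end,
                s_start=1,
                s_end=aa,
                subject_gene_id=gene.gene_id,
                taxon_id=gene.taxon_id,
            )
        )

    for read in community.reads:
        rep_len = catalog.replicons[read.replicon_id].length
        segments = _read_segments(read.start, read.length, rep_len)
        true_hits: list[tuple[GeneRecord, int, int, bool]] = []
        for gene in catalog.genes_on(read.replicon_id):
            ov = _gene_read_overlap(gene, segments)
            if ov is None or ov[1] - ov[0] + 1 < config.min_hit_overlap:
                continue
            q_lo, q_hi = _query_interval(ov[0], ov[1], read, rep_len)
            forward = _hit_is_forward(gene.strand, read.strand)
            true_hits.append((gene, q_lo, q_hi, forward))
            emit(read, gene, q_lo, q_hi, forward,
                 config.true_e_range, 0.55, (75.0, 98.0))
        # homolog hits mirrored into sister species of the same genus
        for sister_id in genus_members[genus_of[read.genome_id]]:
            if sister_id == read.genome_id or not true_hits:
                continue
            if rng.random() >= config.homolog_hit_p:
                continue
            sister_genes = community.catalog.genes_on(f"{sister_id}_chr")
            for gene, q_lo, q_hi, forward in true_hits:
                sister_gene = sister_genes[gene.order_rank]
                emit(read, sister_gene, q_lo, q_hi, forward,
                     config.homolog_e_range, 0.45, (55.0, 85.0))
        # spurious hits to random genes anywhere
        for _ in range(int(rng.poisson(config.spurious_rate))):
            gene = all_genes[int(rng.integers(0, len(all_genes)))]
            span = int(rng.integers(150, 401))
            span = min(span, read.length)
            q_lo = int(rng.integers(1, read.length - span + 2))
            emit(read, gene, q_lo, q_lo + span - 1, bool(rng.random() < 0.5),
                 config.spurious_e_range, 0.2, (40.0, 70.0))
    return HitTable(hits=hits)


def simulate_community(config: SimConfig = SimConfig()) -> SimCommunity:
    """Build a complete synthetic community (genomes, taxonomy, reads, hits)."""
    rng = np.random.default_rng(config.seed)
    tree, species_ids = _build_taxonomy(config)
    catalog = _layout_genomes(config, rng, species_ids)
    community = SimCommunity(config=config, catalog=catalog, tree=tree)
    community.reads = _sample_reads(config, rng, catalog)
    community.hit_table = simulate_hit_table(community, config)
    return community


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

DEFAULT_GRID = tuple(
    (e, n) for e in (1e-2, 1e-4, 1e-6) for n in (50, 150, 250, 350)
)

BENCHMARK_RANKS = ("phylum", "order", "family", "genus")


def run_benchmark(
    community: SimCommunity,
    grid: Sequence[tuple[float, int]] = DEFAULT_GRID,
    base_criteria: BinningCriteria = BinningCriteria(),
    ranks: Sequence[str] = BENCHMARK_RANKS,
) -> pd.DataFrame:
    """Sn/Sp over an (e_max, top_n) criteria grid, with and without adjacency.

    One row per grid cell; for every rank the macro-averaged sensitivity and
    specificity (fractions) of the adjacency method sit next to those of the
    plain-LCA baseline that ignores gene order.
    """
    index = build_adjacency_index(community.catalog)
    truth = community.truth
    rows = []
    for e_max, top_n in grid:
        criteria = replace(base_criteria, e_max=e_max, top_n=top_n)
        with_adj = bin_dataset(
            community.hit_table, index, community.catalog, community.tree, criteria
        )
        without = bin_dataset_plain_lca(community.hit_table, community.tree, criteria)
        row: dict = {"e_max": e_max, "top_n": top_n}
        for label, assignments in (("with", with_adj), ("without", without)):
            table = accuracy_table(assignments, truth, community.tree, ranks)
            for rank in ranks:
                avg = macro_average(table, rank)
                row[f"sn_{rank}_{label}"] = avg["sn"]
                row[f"sp_{rank}_{label}"] = avg["sp"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk fixture export (consumable by the CLI commands unchanged)
# ---------------------------------------------------------------------------

def write_community(community: SimCommunity, out_dir: str) -> dict[str, str]:
    """Write annotations, taxonomy, hits, gene map, truth and reads FASTA."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("annotations", "annotations.tsv"),
        ("taxonomy", "taxonomy.tsv"),
        ("hits", "hits.tsv"),
        ("gene_map", "gene_map.tsv"),
        ("truth", "truth.tsv"),
        ("reads", "reads.fasta"),
    ]}
    cat = community.catalog
    ann = pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "replicon_id": g.replicon_id,
                "taxon_id": g.taxon_id,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "topology": cat.replicons[g.replicon_id].topology,
            }
            for g in cat.genes
        ]
    )
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    tax = pd.DataFrame(
        [
            {"taxon_id": n.taxon_id, "parent_id": n.parent_id, "rank": n.rank, "name": n.name}
            for n in sorted(community.tree.nodes.values(), key=lambda n: n.taxon_id)
        ]
    )
    tax.to_csv(paths["taxonomy"], sep="\t", index=False)
    with open(paths["hits"], "w") as fh:
        for h in community.hit_table.hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.percent_identity, h.align_length,
                        0, 0, h.q_start, h.q_end, h.s_start, h.s_end,
                        repr(h.evalue), h.bit_score,
                    )
                )
                + "\n"
            )
    gm = community.gene_map()
    with open(paths["gene_map"], "w") as fh:
        fh.write("subject_id\tsubject_gene_id\ttaxon_id\n")
        for sid in sorted(gm):
            gene_id, taxon = gm[sid]
            fh.write(f"{sid}\t{gene_id}\t{taxon}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\ttaxon_id\n")
        for r in community.reads:
            fh.write(f"{r.read_id}\t{r.truth_taxon}\n")
    _write_reads_fasta(community, paths["reads"])
    return paths


def _write_reads_fasta(community: SimCommunity, path: str) -> None:
    # sequence content is bookkeeping only (nothing downstream reads it),
    # so bases are drawn at random
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(community.config.seed + 2)
    records = []
    bases = np.array(list("ACGT"))
    for r in community.reads:
        seq = "".join(bases[rng.integers(0, 4, size=r.length)])
        records.append(SeqRecord(Seq(seq), id=r.read_id, description=""))
    seqio_write(records, path, "fasta")
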