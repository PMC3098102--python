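"""Adjacency-consistent pair finding and LCA read assignment.

The consistency logic is checked against a brute-force oracle that
enumerates every hit pair and both read orientations explicitly.
"""

from __future__ import annotations

import numpy as np
import pytest

from adjbin import (
    BinningCriteria,
    GeneCatalog,
    GeneRecord,
    HitTable,
    RepliconMeta,
    assign_read,
    bin_dataset,
    build_adjacency_index,
    cluster_hits_to_loci,
    filter_hits,
    find_consistent_pairs,
)

from conftest import catalog_from_rows, make_hit


@pytest.fixture
def two_genome_catalog(tmp_path):
    """GA (taxon 8): a1(+), a2(+), a3(-); GB (taxon 9): b1(+), b2(+)."""
    return catalog_from_rows(
        tmp_path,
        [
            ("GA", "GA_chr", 8, "a1", 1, 900, "+", "linear"),
            ("GA", "GA_chr", 8, "a2", 1000, 1900, "+", "linear"),
            ("GA", "GA_chr", 8, "a3", 2000, 2900, "-", "linear"),
            ("GB", "GB_chr", 9, "b1", 1, 900, "+", "linear"),
            ("GB", "GB_chr", 9, "b2", 1000, 1900, "+", "linear"),
        ],
    )


def run_pairs(hits, catalog, **kwargs):
    loci = cluster_hits_to_loci(hits)
    index = build_adjacency_index(catalog)
    return find_consistent_pairs(hits, loci, index, catalog, **kwargs)


class TestFindConsistentPairs:
    def test_matching_arrangement_is_consistent(self, two_genome_catalog):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a2", taxon=8, q_lo=400, q_hi=700, strand="+"),
        ]
        (pair,) = run_pairs(hits, two_genome_catalog)
        assert pair.consistent
        assert (pair.gene_a, pair.gene_b) == ("a1", "a2")
        assert pair.direction.value == "unidirectional"

    def test_swapped_order_without_strand_flip_is_inconsistent(
        self, two_genome_catalog
    ):
        # genes in reverse genomic order but strands unchanged: of the eight
        # order x strand arrangements only two are consistent, this is neither
        hits = [
            make_hit(gene="a2", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a1", taxon=8, q_lo=400, q_hi=700, strand="+"),
        ]
        (pair,) = run_pairs(hits, two_genome_catalog)
        assert not pair.consistent

    def test_reverse_complemented_read_is_consistent(self, two_genome_catalog):
        # same fragment sequenced from the other strand: order swapped AND
        # both strands flipped
        hits = [
            make_hit(gene="a2", taxon=8, q_lo=1, q_hi=300, strand="-"),
            make_hit(gene="a1", taxon=8, q_lo=400, q_hi=700, strand="-"),
        ]
        (pair,) = run_pairs(hits, two_genome_catalog)
        assert pair.consistent

    def test_non_adjacent_genes_are_not_emitted(self, two_genome_catalog):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a3", taxon=8, q_lo=400, q_hi=700, strand="-"),
        ]
        assert run_pairs(hits, two_genome_catalog) == []

    def test_same_locus_hits_are_never_paired(self, two_genome_catalog):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a2", taxon=8, q_lo=1, q_hi=300, strand="+"),
        ]
        assert run_pairs(hits, two_genome_catalog) == []

    def test_cross_taxon_hits_are_never_paired(self, two_genome_catalog):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="b2", taxon=9, q_lo=400, q_hi=700, strand="+"),
        ]
        assert run_pairs(hits, two_genome_catalog) == []

    def test_direction_mode_accepts_same_class_different_order(
        self, two_genome_catalog
    ):
        hits = [
            make_hit(gene="a2", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a1", taxon=8, q_lo=400, q_hi=700, strand="+"),
        ]
        (strict,) = run_pairs(hits, two_genome_catalog, arrangement_mode="full")
        (relaxed,) = run_pairs(hits, two_genome_catalog, arrangement_mode="direction")
        assert not strict.consistent
        assert relaxed.consistent  # both unidirectional


class TestAssignRead:
    def test_single_species_support(self, two_genome_catalog, seven_rank_tree):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a2", taxon=8, q_lo=400, q_hi=700, strand="+"),
        ]
        pairs = run_pairs(hits, two_genome_catalog)
        a = assign_read(pairs, seven_rank_tree)
        assert a.assigned and a.taxon_id == 8
        assert a.rank_projections["species"] == 8
        assert a.rank_projections["phylum"] == 3

    def test_two_species_meet_at_genus(self, two_genome_catalog, seven_rank_tree):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a2", taxon=8, q_lo=400, q_hi=700, strand="+"),
            make_hit(gene="b1", taxon=9, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="b2", taxon=9, q_lo=400, q_hi=700, strand="+"),
        ]
        pairs = run_pairs(hits, two_genome_catalog)
        a = assign_read(pairs, seven_rank_tree)
        assert a.taxon_id == 7  # the shared genus
        assert a.rank_projections["species"] is None
        assert a.supporting_taxa == frozenset({8, 9})

    def test_no_consistent_pairs_means_unclassified(self, seven_rank_tree):
        a = assign_read([], seven_rank_tree)
        assert a.status == "unclassified" and a.n_consistent_pairs == 0

    def test_min_support_gates_assignment(
        self, two_genome_catalog, seven_rank_tree
    ):
        hits = [
            make_hit(gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
            make_hit(gene="a2", taxon=8, q_lo=400, q_hi=700, strand="+"),
        ]
        pairs = run_pairs(hits, two_genome_catalog)
        assert assign_read(pairs, seven_rank_tree, min_support=2).status == "unclassified"


class TestBinDataset:
    def _table(self):
        return HitTable(
            hits=[
                make_hit(query="r1", gene="a1", taxon=8, q_lo=1, q_hi=300, strand="+"),
                make_hit(query="r1", gene="a2", taxon=8, q_lo=400, q_hi=700, strand="+"),
                # r2's only hit fails the E-value cut-off
                make_hit(query="r2", gene="a1", taxon=8, evalue=1e-3),
            ]
        )

    def test_assigned_and_unclassified_reads(self, two_genome_catalog, seven_rank_tree):
        index = build_adjacency_index(two_genome_catalog)
        out = bin_dataset(self._table(), index, two_genome_catalog, seven_rank_tree)
        by_id = {a.read_id: a for a in out}
        assert by_id["r1"].assigned and by_id["r1"].taxon_id == 8
        assert by_id["r2"].status == "unclassified"
        assert [a.read_id for a in out] == ["r1", "r2"]

    def test_empty_table_gives_no_assignments(self, two_genome_catalog, seven_rank_tree):
        index = build_adjacency_index(two_genome_catalog)
        assert bin_dataset(HitTable(), index, two_genome_catalog, seven_rank_tree) == []

    def test_identical_runs_are_identical(self, two_genome_catalog, seven_rank_tree):
        index = build_adjacency_index(two_genome_catalog)
        a = bin_dataset(self._table(), index, two_genome_catalog, seven_rank_tree)
        b = bin_dataset(self._table(), index, two_genome_catalog, seven_rank_tree)
        assert a == b

    def test_single_locus_reads_are_unclassified(
        self, two_genome_catalog, seven_rank_tree
    ):
        table = HitTable(
            hits=[make_hit(query="r1", gene="a1", taxon=8, q_lo=1, q_hi=300)]
        )
        index = build_adjacency_index(two_genome_catalog)
        (a,) = bin_dataset(table, index, two_genome_catalog, seven_rank_tree)
        assert a.status == "unclassified"


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

FLIP = {"+": "-", "-": "+"}


def oracle_adjacency(catalog: GeneCatalog):
    """Recompute adjacency naively from coordinates and topology."""
    adj = {}
    by_rep: dict[str, list[GeneRecord]] = {}
    for g in catalog.genes:
        by_rep.setdefault(g.replicon_id, []).append(g)
    for rep, genes in by_rep.items():
        genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        pairs = list(zip(genes, genes[1:]))
        if catalog.replicons[rep].topology == "circular" and len(genes) >= 3:
            pairs.append((genes[-1], genes[0]))
        for a, b in pairs:
            adj[frozenset((a.gene_id, b.gene_id))] = (
                (a.gene_id, a.strand),
                (b.gene_id, b.strand),
            )
    return adj


def oracle_pairs(hits, loci, catalog):
    """Enumerate every hit pair and both read orientations explicitly.

    Returns {(taxon, frozenset{gene_a, gene_b}): consistent?} for every
    adjacent pair tested.
    """
    adj = oracle_adjacency(catalog)
    locus_of = {id(h): i for i, locus in enumerate(loci) for h in locus.hits}
    by_taxon: dict[int, list] = {}
    for h in hits:
        by_taxon.setdefault(h.taxon_id, []).append(h)
    result: dict = {}
    for taxon, taxon_hits in by_taxon.items():
        for i in range(len(taxon_hits)):
            for j in range(i + 1, len(taxon_hits)):
                ha, hb = taxon_hits[i], taxon_hits[j]
                if locus_of[id(ha)] == locus_of[id(hb)]:
                    continue
                if ha.subject_gene_id == hb.subject_gene_id:
                    continue
                key = frozenset((ha.subject_gene_id, hb.subject_gene_id))
                if key not in adj:
                    continue
                ref = adj[key]
                first, second = sorted((ha, hb), key=lambda h: locus_of[id(h)])
                as_is = (
                    (first.subject_gene_id, first.read_strand),
                    (second.subject_gene_id, second.read_strand),
                )
                rc = (
                    (as_is[1][0], FLIP[as_is[1][1]]),
                    (as_is[0][0], FLIP[as_is[0][1]]),
                )
                ok = as_is == ref or rc == ref
                k = (taxon, key)
                result[k] = result.get(k, False) or ok
    return result


def random_instance(rng):
    """A random catalog plus the hits of one read (<= 50 hits, <= 5 taxa)."""
    n_genomes = int(rng.integers(1, 5))
    genes, replicons, genome_taxon = [], {}, {}
    for gi in range(n_genomes):
        genome, rep = f"G{gi}", f"G{gi}_chr"
        topology = "circular" if rng.random() < 0.5 else "linear"
        n_genes = int(rng.integers(2, 9))
        pos = 1
        for j in range(n_genes):
            length = int(rng.integers(100, 600))
            genes.append(
                GeneRecord(
                    genome_id=genome,
                    replicon_id=rep,
                    taxon_id=100 + gi,
                    gene_id=f"G{gi}_g{j}",
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    order_rank=j,
                )
            )
            pos += length + int(rng.integers(1, 300))
        replicons[rep] = RepliconMeta(rep, pos, topology)
        genome_taxon[genome] = 100 + gi
    catalog = GeneCatalog(genes=genes, replicons=replicons, genome_taxon=genome_taxon)

    n_loci = int(rng.integers(0, 6))
    hits = []
    for li in range(n_loci):
        lo = 1 + 400 * li
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(int(rng.integers(1, 5))):
            g = genes[int(rng.integers(0, len(genes)))]
            hits.append(
                make_hit(
                    query="r",
                    gene=g.gene_id,
                    taxon=g.taxon_id,
                    q_lo=lo,
                    q_hi=lo + 300,
                    strand=strand,
                    evalue=float(10.0 ** -rng.integers(6, 40)),
                    bit=float(rng.integers(30, 400)),
                )
            )
    return catalog, hits[:50]


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            catalog, hits = random_instance(rng)
            loci = cluster_hits_to_loci(hits)
            index = build_adjacency_index(catalog)
            got = {
                (p.taxon_id, frozenset((p.gene_a, p.gene_b))): p.consistent
                for p in find_consistent_pairs(hits, loci, index, catalog)
            }
            expected = oracle_pairs(hits, loci, catalog)
            assert got == expected

    def test_orientation_symmetry(self):
        # reverse-complementing the whole read leaves every label unchanged
        rng = np.random.default_rng(7)
        read_len = 4000
        for _ in range(200):
            catalog, hits = random_instance(rng)
            flipped = [
                make_hit(
                    query="r",
                    gene=h.subject_gene_id,
                    taxon=h.taxon_id,
                    q_lo=read_len - h.q_hi + 1,
                    q_hi=read_len - h.q_lo + 1,
                    strand=FLIP[h.read_strand],
                    evalue=h.evalue,
                    bit=h.bit_score,
                )
                for h in hits
            ]
            index = build_adjacency_index(catalog)

            def labels(hs):
                loci = cluster_hits_to_loci(hs)
                return {
                    (p.taxon_id, frozenset((p.gene_a, p.gene_b))): p.consistent
                    for p in find_consistent_pairs(hs, loci, index, catalog)
                }

            assert labels(hits) == labels(flipped)

    def test_consistent_pair_set_is_monotone_in_top_n(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            catalog, hits = random_instance(rng)
            index = build_adjacency_index(catalog)
            table = HitTable(hits=hits)

            def consistent_at(top_n):
                kept = filter_hits(table, e_max=1e-3, top_n=top_n).hits
                loci = cluster_hits_to_loci(kept)
                return {
                    (p.taxon_id, frozenset((p.gene_a, p.gene_b)))
                    for p in find_consistent_pairs(kept, loci, index, catalog)
                    if p.consistent
                }

            assert consistent_at(5) <= consistent_at(15)
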