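"""The adjacency-aware binning method.

A read that carries two (or more) candidate coding loci is assigned by
asking which reference taxa contain the two hit genes *directly next to
each other* with the same transcriptional arrangement the read shows.
Concretely, per taxon the read's filtered hits are compared pairwise
across distinct loci; a pair is *consistent* when

1. the two subject genes are adjacent on one replicon of that taxon, and
2. the read-side arrangement — order of the two loci along the read plus
   their read strands — equals the reference arrangement (genomic order
   plus gene strands), either for the read as-is or for its reverse
   complement (shotgun read orientation is arbitrary).

Adjacent pairs failing (2) are the "inconsistent genomic arrangement"
pairs and are removed.  The taxa supported by at least one consistent pair
feed a plain lowest-common-ancestor assignment; a read with no consistent
pair stays unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .hit_processing import (
    BlastHit,
    CdsLocus,
    HitTable,
    cluster_hits_to_loci,
    filter_hits,
)
from .reference_index import (
    AdjacencyIndex,
    DirectionClass,
    GeneCatalog,
    direction_from_strands,
)
from .taxonomy import CANONICAL_RANKS, TaxonomyTree, lca, project_to_rank

FORWARD = "+"
REVERSE = "-"

_FLIP = {FORWARD: REVERSE, REVERSE: FORWARD}


@dataclass(frozen=True)
class BinningCriteria:
    """Tunable filtering/assignment thresholds of the pipeline."""

    e_max: float = 1e-5
    top_n: int = 250
    max_overlap_fraction: float = 0.5
    min_support: int = 1
    #: "full" demands order+strand arrangement equality (up to global
    #: reverse complement); "direction" relaxes to direction-class equality.
    arrangement_mode: str = "full"


@dataclass(frozen=True)
class AdjacentPairEvidence:
    """One tested adjacent gene pair for one read and one taxon."""

    read_id: str
    taxon_id: int
    genome_id: str
    replicon_id: str
    gene_a: str  # genomically first gene of the reference pair
    gene_b: str
    direction: DirectionClass
    read_arrangement: tuple  # ((gene, strand), (gene, strand)) in read order
    consistent: bool


@dataclass
class Assignment:
    """Per-read binning outcome with rank projections and evidence counts."""

    read_id: str
    status: str  # "assigned" | "unclassified"
    taxon_id: Optional[int] = None
    rank_projections: dict[str, Optional[int]] = field(default_factory=dict)
    supporting_taxa: frozenset = frozenset()
    n_consistent_pairs: int = 0

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def _arrangement_consistent(
    ref: tuple[tuple[str, str], tuple[str, str]],
    read: tuple[tuple[str, str], tuple[str, str]],
    mode: str,
) -> bool:
    """Does the read-side arrangement match the reference one?

    Both arrangements are ((gene, strand), (gene, strand)) ordered by
    position.  The read is accepted as-is or reverse-complemented (order
    flipped, strands flipped).
    """
    (g1, s1), (g2, s2) = read
    read_rc = ((g2, _FLIP[s2]), (g1, _FLIP[s1]))
    if mode == "full":
        return read == ref or read_rc == ref
    if mode == "direction":
        ref_dir = direction_from_strands(ref[0][1], ref[1][1])
        read_dir = direction_from_strands(s1, s2)
        return read_dir == ref_dir  # direction class is RC-invariant
    raise ValueError(f"unknown arrangement_mode {mode!r}")


def find_consistent_pairs(
    read_hits: Iterable[BlastHit],
    loci: list[CdsLocus],
    index: AdjacencyIndex,
    catalog: GeneCatalog,
    arrangement_mode: str = "full",
) -> list[AdjacentPairEvidence]:
    """Test every cross-locus hit pair of each taxon against the reference.

    Hits are grouped by taxon; within a taxon every unordered pair of hits
    from *distinct* loci and to *distinct* genes is looked up in the
    adjacency index.  Non-adjacent gene pairs are not emitted; adjacent
    pairs are emitted flagged consistent or removed-inconsistent.  Evidence
    is deduplicated at the (taxon, gene_a, gene_b) level — a pair counts as
    consistent if any hit combination supports it — and ordered by
    (taxon_id, gene_a, gene_b).
    """
    read_hits = list(read_hits)
    if not read_hits:
        return []
    read_id = read_hits[0].query_id

    # locus membership by object identity (loci partition the hit set)
    locus_of: dict[int, int] = {}
    for li, locus in enumerate(loci):
        for h in locus.hits:
            locus_of[id(h)] = li

    by_taxon: dict[int, list[BlastHit]] = {}
    for h in read_hits:
        by_taxon.setdefault(h.taxon_id, []).append(h)

    best: dict[tuple[int, str, str], AdjacentPairEvidence] = {}
    for taxon_id in sorted(by_taxon):
        hits = by_taxon[taxon_id]
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                ha, hb = hits[i], hits[j]
                la, lb = locus_of.get(id(ha)), locus_of.get(id(hb))
                if la is None or lb is None or la == lb:
                    continue  # same CDS (or hit not in any locus): not a pair
                if ha.subject_gene_id == hb.subject_gene_id:
                    continue
                info = index.lookup(ha.subject_gene_id, hb.subject_gene_id)
                if info is None:
                    continue
                ref = ((info.first, info.first_strand), (info.second, info.second_strand))
                # loci arrive position-sorted, so index order is read order
                # (ties broken by (lo, hi, strand) in cluster_hits_to_loci)
                first, second = (ha, hb) if la < lb else (hb, ha)
                read_arr = (
                    (first.subject_gene_id, first.read_strand),
                    (second.subject_gene_id, second.read_strand),
                )
                ok = _arrangement_consistent(ref, read_arr, arrangement_mode)
                key = (taxon_id, info.first, info.second)
                prev = best.get(key)
                if prev is None or (ok and not prev.consistent):
                    best[key] = AdjacentPairEvidence(
                        read_id=read_id,
                        taxon_id=taxon_id,
                        genome_id=info.genome_id,
                        replicon_id=info.replicon_id,
                        gene_a=info.first,
                        gene_b=info.second,
                        direction=info.direction,
                        read_arrangement=read_arr,
                        consistent=ok,
                    )
    return [best[k] for k in sorted(best)]


def assign_read(
    pairs: Iterable[AdjacentPairEvidence],
    tree: TaxonomyTree,
    min_support: int = 1,
) -> Assignment:
    """LCA assignment of one read from its consistent adjacent-pair evidence."""
    pairs = list(pairs)
    read_id = pairs[0].read_id if pairs else ""
    taxa = frozenset(p.taxon_id for p in pairs if p.consistent)
    n_consistent = sum(1 for p in pairs if p.consistent)
    if not taxa or len(taxa) < min_support:
        return Assignment(read_id=read_id, status="unclassified")
    assigned = lca(tree, taxa)
    projections = {r: project_to_rank(tree, assigned, r) for r in CANONICAL_RANKS}
    return Assignment(
        read_id=read_id,
        status="assigned",
        taxon_id=assigned,
        rank_projections=projections,
        supporting_taxa=taxa,
        n_consistent_pairs=n_consistent,
    )


def bin_dataset(
    hit_table: HitTable,
    index: AdjacencyIndex,
    catalog: GeneCatalog,
    tree: TaxonomyTree,
    criteria: BinningCriteria = BinningCriteria(),
) -> list[Assignment]:
    """Run the full pipeline over every query in a hit table.

    filter -> locus clustering -> consistent-pair search -> LCA, yielding
    one Assignment per query_id (unclassified ones included), ordered by
    read_id.  Deterministic for identical inputs.
    """
    filtered = filter_hits(hit_table, e_max=criteria.e_max, top_n=criteria.top_n)
    grouped = filtered.by_query()
    assignments: list[Assignment] = []
    for read_id in sorted(hit_table.query_ids()):
        hits = grouped.get(read_id, [])
        if not hits:
            assignments.append(Assignment(read_id=read_id, status="unclassified"))
            continue
        loci = cluster_hits_to_loci(hits, criteria.max_overlap_fraction)
        pairs = find_consistent_pairs(
            hits, loci, index, catalog, arrangement_mode=criteria.arrangement_mode
        )
        result = assign_read(pairs, tree, min_support=criteria.min_support)
        if not result.read_id:
            result.read_id = read_id
        assignments.append(result)
    return assignments


def bin_dataset_plain_lca(
    hit_table: HitTable,
    tree: TaxonomyTree,
    criteria: BinningCriteria = BinningCriteria(),
) -> list[Assignment]:
    """Baseline without the adjacency criterion: LCA over all filtered hits.

    Every read with at least one hit surviving the E-value/top-N filter is
    assigned to the LCA of its hits' taxa — the comparison mode for
    quantifying what the adjacency requirement buys.
    """
    filtered = filter_hits(hit_table, e_max=criteria.e_max, top_n=criteria.top_n)
    grouped = filtered.by_query()
    assignments: list[Assignment] = []
    for read_id in sorted(hit_table.query_ids()):
        hits = grouped.get(read_id, [])
        taxa = frozenset(h.taxon_id for h in hits)
        if not taxa:
            assignments.append(Assignment(read_id=read_id, status="unclassified"))
            continue
        assigned = lca(tree, taxa)
        projections = {r: project_to_rank(tree, assigned, r) for r in CANONICAL_RANKS}
        assignments.append(
            Assignment(
                read_id=read_id,
                status="assigned",
                taxon_id=assigned,
                rank_projections=projections,
                supporting_taxa=taxa,
                n_consistent_pairs=0,
            )
        )
    return assignments
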