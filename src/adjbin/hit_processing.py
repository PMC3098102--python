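"""BLAST tabular hit parsing, E-value/top-N filtering, and CDS locus calling.

Translated homology searches of ~1 kb shotgun fragments against a reference
protein set yield many hits per read.  The binning method keeps a generous
hit list per read (E <= e_max, then the ``top_n`` best by bit score) rather
than only the best hit, because adjacency evidence needs hits to *both*
genes of a neighboring pair.  Hits are then clustered along the read into
candidate coding loci (CDSs): single-linkage over query intervals, merging
two hits only when they lie on the same read strand and their overlap
exceeds a fraction of the shorter interval.  The number of loci on a read
is that read's CDS count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import ParseError

#: BLAST "outfmt 6" column order.
OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class BlastHit:
    """One parsed tabular hit with its subject resolved to a reference gene.

    ``q_start > q_end`` encodes a reverse-strand (negative frame) hit on the
    read, as BLASTX prints it.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bit_score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_gene_id: str
    taxon_id: int

    @property
    def read_strand(self) -> str:
        return FORWARD if self.q_start <= self.q_end else REVERSE

    @property
    def q_lo(self) -> int:
        return min(self.q_start, self.q_end)

    @property
    def q_hi(self) -> int:
        return max(self.q_start, self.q_end)

    @property
    def q_span(self) -> int:
        return self.q_hi - self.q_lo + 1


@dataclass
class HitTable:
    """Hits grouped by query, preserving a stable per-query order."""

    hits: list[BlastHit] = field(default_factory=list)
    n_unmapped_subjects: int = 0

    def __len__(self) -> int:
        return len(self.hits)

    def query_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.hits:
            seen.setdefault(h.query_id, None)
        return list(seen)

    def by_query(self) -> dict[str, list[BlastHit]]:
        grouped: dict[str, list[BlastHit]] = {}
        for h in self.hits:
            grouped.setdefault(h.query_id, []).append(h)
        return grouped


@dataclass
class CdsLocus:
    """A candidate coding locus on a read: the union of its member hits."""

    query_id: str
    lo: int
    hi: int
    strand: str
    hits: list[BlastHit] = field(default_factory=list)


def parse_blast_tabular(
    path: str, gene_map: Mapping[str, tuple[str, int]]
) -> HitTable:
    """Parse a 12-column BLAST tabular file ("outfmt 6").

    ``gene_map`` resolves each subject id to ``(subject_gene_id, taxon_id)``;
    hits whose subject is absent from the map are dropped (their count is
    kept on the returned table).  '#' comment lines are allowed.
    """
    hits: list[BlastHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}, line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-numeric field ({exc})") from None
            if min(qstart, qend) < 1:
                raise ParseError(f"{path}, line {lineno}: query positions must be >= 1")
            if evalue < 0:
                raise ParseError(f"{path}, line {lineno}: negative E-value")
            if sseqid not in gene_map:
                dropped += 1
                continue
            gene_id, taxon_id = gene_map[sseqid]
            hits.append(
                BlastHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    percent_identity=pident,
                    align_length=length,
                    evalue=evalue,
                    bit_score=bitscore,
                    q_start=qstart,
                    q_end=qend,
                    s_start=sstart,
                    s_end=send,
                    subject_gene_id=gene_id,
                    taxon_id=int(taxon_id),
                )
            )
    return HitTable(hits=hits, n_unmapped_subjects=dropped)


def load_gene_map(path: str) -> dict[str, tuple[str, int]]:
    """TSV ``subject_id  subject_gene_id  taxon_id`` (header optional)."""
    mapping: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}, line {lineno}: expected 3 columns")
            if lineno == 1 and fields[0] == "subject_id":
                continue
            mapping[fields[0]] = (fields[1], int(fields[2]))
    return mapping


def filter_hits(table: HitTable, e_max: float = 1e-5, top_n: int = 250) -> HitTable:
    """Per query: keep hits with E <= e_max, rank by bit score, keep the top N.

    Ranking is bit score descending with deterministic tie-breaks (E-value
    ascending, then subject id lexicographic); truncation to ``top_n`` is
    therefore nested across increasing N.
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    kept: list[BlastHit] = []
    for _, hits in table.by_query().items():
        passing = [h for h in hits if h.evalue <= e_max]
        passing.sort(key=lambda h: (-h.bit_score, h.evalue, h.subject_id))
        kept.extend(passing[:top_n])
    return HitTable(hits=kept, n_unmapped_subjects=table.n_unmapped_subjects)


def cluster_hits_to_loci(
    hits: Iterable[BlastHit], max_overlap_fraction: float = 0.5
) -> list[CdsLocus]:
    """Single-linkage clustering of one read's hits into candidate CDS loci.

    Two hits join the same locus iff they lie on the same read strand and
    their query-interval overlap exceeds ``max_overlap_fraction`` of the
    shorter interval.  Opposite-strand hits never merge (overlapping genes
    on opposite strands are genuine).  Every hit lands in exactly one locus;
    a locus interval is the union of its members' intervals.
    """
    hits = list(hits)
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")

    parent = list(range(len(hits)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if a.read_strand != b.read_strand:
                continue
            overlap = min(a.q_hi, b.q_hi) - max(a.q_lo, b.q_lo) + 1
            shorter = min(a.q_span, b.q_span)
            if overlap > max_overlap_fraction * shorter:
                union(i, j)

    clusters: dict[int, list[BlastHit]] = {}
    for i, h in enumerate(hits):
        clusters.setdefault(find(i), []).append(h)
    loci = [
        CdsLocus(
            query_id=members[0].query_id,
            lo=min(h.q_lo for h in members),
            hi=max(h.q_hi for h in members),
            strand=members[0].read_strand,
            hits=members,
        )
        for members in clusters.values()
    ]
    loci.sort(key=lambda loc: (loc.lo, loc.hi, loc.strand))
    return loci
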