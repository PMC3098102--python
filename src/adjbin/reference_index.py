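"""Reference gene catalog and the gene-adjacency index.

Prokaryotic gene order is locally conserved, so two genes that sit directly
next to each other on a replicon carry taxonomic signal beyond what either
gene's homology score provides.  This module loads reference gene
annotations (GFF3 or a simple TSV dialect), orders genes along each
replicon, and records every adjacent gene pair together with its
transcriptional direction class:

* ``unidirectional`` — both genes on the same strand (-> ->),
* ``convergent``     — first on forward, second on reverse (-> <-),
* ``divergent``      — first on reverse, second on forward (<- ->).

Coordinates are 1-based inclusive throughout, matching GFF3 and BLAST.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import ParseError, ValidationError

FORWARD = "+"
REVERSE = "-"

_TSV_COLUMNS = [
    "genome_id",
    "replicon_id",
    "taxon_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "topology",
]


class DirectionClass(str, Enum):
    """Relative transcriptional arrangement of an adjacent gene pair."""

    UNIDIRECTIONAL = "unidirectional"
    CONVERGENT = "convergent"
    DIVERGENT = "divergent"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a replicon.

    ``order_rank`` is the 0-based position of the gene along its replicon when
    genes are sorted by ascending start (ties: ascending end, then gene_id).
    """

    genome_id: str
    replicon_id: str
    taxon_id: int
    gene_id: str
    start: int
    end: int
    strand: str
    order_rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepliconMeta:
    """Replicon bookkeeping: a chromosome or plasmid and its topology."""

    replicon_id: str
    length: int
    topology: str = "linear"  # "linear" or "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValidationError(
                f"replicon {self.replicon_id!r}: topology must be linear|circular"
            )


@dataclass
class GeneCatalog:
    """The reference gene set: genes with replicon order plus replicon metadata."""

    genes: list[GeneRecord] = field(default_factory=list)
    replicons: dict[str, RepliconMeta] = field(default_factory=dict)
    genome_taxon: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_replicon: dict[str, list[GeneRecord]] = {}
        self._by_gene_id: dict[str, GeneRecord] = {}
        for g in self.genes:
            self._by_replicon.setdefault(g.replicon_id, []).append(g)
            self._by_gene_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        """Genes of one replicon in order_rank order."""
        return sorted(self._by_replicon.get(replicon_id, []), key=lambda g: g.order_rank)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_gene_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._by_gene_id

    @property
    def replicon_ids(self) -> list[str]:
        return sorted(self.replicons)


@dataclass(frozen=True)
class AdjacencyInfo:
    """One adjacent gene pair, oriented by the genomic walk direction.

    ``first``/``second`` give the pair in ascending genomic order (for the
    circular wrap-around pair, ``first`` is the last gene before the origin).
    ``direction`` is the pair's DirectionClass in that orientation, and
    ``first_strand``/``second_strand`` record the exact strand arrangement.
    """

    genome_id: str
    replicon_id: str
    first: str
    second: str
    first_strand: str
    second_strand: str
    direction: DirectionClass


class AdjacencyIndex:
    """Symmetric "directly next to each other" relation over reference genes."""

    def __init__(self) -> None:
        self._pairs: dict[frozenset, AdjacencyInfo] = {}
        self._neighbors: dict[str, set[str]] = {}

    def add(self, info: AdjacencyInfo) -> None:
        key = frozenset((info.first, info.second))
        self._pairs[key] = info
        self._neighbors.setdefault(info.first, set()).add(info.second)
        self._neighbors.setdefault(info.second, set()).add(info.first)

    def lookup(self, gene_a: str, gene_b: str) -> Optional[AdjacencyInfo]:
        """The adjacency record for an unordered gene pair, or None."""
        return self._pairs.get(frozenset((gene_a, gene_b)))

    def are_adjacent(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self._pairs

    def neighbors(self, gene_id: str) -> set[str]:
        return set(self._neighbors.get(gene_id, ()))

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[AdjacencyInfo]:
        return iter(sorted(self._pairs.values(), key=lambda p: (p.replicon_id, p.first, p.second)))


def direction_from_strands(strand_first: str, strand_second: str) -> DirectionClass:
    """Direction class of an ordered strand pair (first gene upstream of second)."""
    if strand_first == strand_second:
        return DirectionClass.UNIDIRECTIONAL
    if strand_first == FORWARD:
        return DirectionClass.CONVERGENT
    return DirectionClass.DIVERGENT


def direction_class(a: GeneRecord, b: GeneRecord) -> DirectionClass:
    """Direction class of two genes taken in genomic order (a upstream of b)."""
    if a.gene_id == b.gene_id:
        raise ValidationError(f"direction_class needs two distinct genes, got {a.gene_id!r} twice")
    return direction_from_strands(a.strand, b.strand)


# ---------------------------------------------------------------------------
# Annotation loading
# ---------------------------------------------------------------------------

def _assign_order_ranks(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort genes per replicon by (start, end, gene_id) and stamp order_rank."""
    ranked: list[GeneRecord] = []
    by_rep: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_rep.setdefault((g.genome_id, g.replicon_id), []).append(g)
    for _, members in sorted(by_rep.items()):
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(members):
            ranked.append(replace(g, order_rank=rank))
    return ranked


def _finalize_catalog(
    genes: list[GeneRecord], topologies: dict[str, str]
) -> GeneCatalog:
    seen: dict[tuple[str, str], None] = {}
    for g in genes:
        key = (g.genome_id, g.gene_id)
        if key in seen:
            raise ValidationError(
                f"duplicate gene_id {g.gene_id!r} within genome {g.genome_id!r}"
            )
        seen[key] = None
    genome_taxon: dict[str, int] = {}
    for g in genes:
        prev = genome_taxon.setdefault(g.genome_id, g.taxon_id)
        if prev != g.taxon_id:
            raise ValidationError(
                f"genome {g.genome_id!r} maps to taxa {prev} and {g.taxon_id}"
            )
    ranked = _assign_order_ranks(genes)
    replicons = {}
    max_end: dict[str, int] = {}
    for g in ranked:
        max_end[g.replicon_id] = max(max_end.get(g.replicon_id, 0), g.end)
    for rep_id, end in max_end.items():
        replicons[rep_id] = RepliconMeta(
            replicon_id=rep_id,
            length=end,
            topology=topologies.get(rep_id, "linear"),
        )
    return GeneCatalog(genes=ranked, replicons=replicons, genome_taxon=genome_taxon)


def _load_tsv(path: str) -> GeneCatalog:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        return GeneCatalog()
    missing = [c for c in _TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    genes: list[GeneRecord] = []
    topologies: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict()
        for col in _TSV_COLUMNS[:-1]:
            if rec[col] == "":
                raise ParseError(f"{path}, line {i}: empty mandatory field {col!r}")
        try:
            start, end = int(rec["start"]), int(rec["end"])
            taxon = int(rec["taxon_id"])
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: non-numeric field ({exc})") from None
        try:
            genes.append(
                GeneRecord(
                    genome_id=rec["genome_id"],
                    replicon_id=rec["replicon_id"],
                    taxon_id=taxon,
                    gene_id=rec["gene_id"],
                    start=start,
                    end=end,
                    strand=rec["strand"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from None
        topo = rec.get("topology", "") or "linear"
        topologies[rec["replicon_id"]] = topo
    return _finalize_catalog(genes, topologies)


def _load_gff3(path: str, feature_type: str) -> GeneCatalog:
    # GFF3's fixed columns carry no genome or taxon identifiers; we read them
    # from the attribute column (genome_id=..., taxon_id=..., topology=...),
    # defaulting genome_id to the seqid.
    from gffutils import feature as gff_feature

    genes: list[GeneRecord] = []
    topologies: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gff_feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            if feat.featuretype != feature_type:
                continue
            attrs = feat.attributes
            if "ID" not in attrs:
                raise ParseError(f"{path}, line {lineno}: feature lacks an ID attribute")
            if "taxon_id" not in attrs:
                raise ParseError(f"{path}, line {lineno}: feature lacks a taxon_id attribute")
            genome_id = attrs["genome_id"][0] if "genome_id" in attrs else feat.seqid
            try:
                genes.append(
                    GeneRecord(
                        genome_id=genome_id,
                        replicon_id=feat.seqid,
                        taxon_id=int(attrs["taxon_id"][0]),
                        gene_id=attrs["ID"][0],
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            if "topology" in attrs:
                topologies[feat.seqid] = attrs["topology"][0]
    return _finalize_catalog(genes, topologies)


def load_gene_annotations(
    path: str, format: str = "tsv", feature_type: str = "gene"
) -> GeneCatalog:
    """Load reference gene annotations into a GeneCatalog.

    Parameters
    ----------
    path:
        Annotation file. TSV dialect: tab-separated with a header line
        ``genome_id replicon_id taxon_id gene_id start end strand [topology]``;
        '#' comment lines are ignored. GFF3: seqid is the replicon,
        the ``ID`` attribute is the gene_id.
    format:
        ``"tsv"`` or ``"gff3"``.
    feature_type:
        GFF3 feature type to keep (``"gene"`` or ``"CDS"``).
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "gff3":
        return _load_gff3(path, feature_type)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Adjacency index construction
# ---------------------------------------------------------------------------

def build_adjacency_index(catalog: GeneCatalog) -> AdjacencyIndex:
    """Record every directly-adjacent gene pair per replicon.

    Adjacency is consecutive ``order_rank`` on one replicon; on a circular
    replicon with at least three genes the (last, first) pair wrapping the
    origin is adjacent as well.  Pairs never cross replicons, so plasmid and
    chromosome genes of one genome are never adjacent to each other.
    """
    index = AdjacencyIndex()
    for rep_id in catalog.replicon_ids:
        genes = catalog.genes_on(rep_id)
        if len(genes) < 2:
            continue
        pairs = list(zip(genes, genes[1:]))
        meta = catalog.replicons[rep_id]
        if meta.topology == "circular" and len(genes) >= 3:
            pairs.append((genes[-1], genes[0]))
        for a, b in pairs:
            index.add(
                AdjacencyInfo(
                    genome_id=a.genome_id,
                    replicon_id=rep_id,
                    first=a.gene_id,
                    second=b.gene_id,
                    first_strand=a.strand,
                    second_strand=b.strand,
                    direction=direction_from_strands(a.strand, b.strand),
                )
            )
    return index


# ---------------------------------------------------------------------------
# Catalog/index round-trip (used by the CLI `index` command)
# ---------------------------------------------------------------------------

def save_catalog(catalog: GeneCatalog, path: str) -> None:
    """Serialize a catalog (genes + replicon topology) as JSON."""
    payload = {
        "genes": [
            {
                "genome_id": g.genome_id,
                "replicon_id": g.replicon_id,
                "taxon_id": g.taxon_id,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in catalog.genes
        ],
        "replicons": {
            r.replicon_id: {"length": r.length, "topology": r.topology}
            for r in catalog.replicons.values()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_catalog(path: str) -> GeneCatalog:
    with open(path) as fh:
        payload = json.load(fh)
    genes = [GeneRecord(**rec) for rec in payload["genes"]]
    topologies = {rid: meta["topology"] for rid, meta in payload["replicons"].items()}
    return _finalize_catalog(genes, topologies)
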