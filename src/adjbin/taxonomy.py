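"""Reference taxonomy: loading, lowest-common-ancestor, rank projection.

The tree follows the NCBI taxonomy model: every node has a parent, a rank
label and a name; the root is its own parent.  Rank labels used for
projection are the seven canonical prokaryotic ranks; any other label
(``no rank`` included) is transparent — projection walks through such nodes,
while the LCA may land on one and reports it with its own label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ParseError, ValidationError

#: Canonical ranks, root-most first.
CANONICAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NO_RANK = "no rank"


@dataclass(frozen=True)
class TaxNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str = ""


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent pointers keyed by integer taxon id."""

    nodes: dict[int, TaxNode]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError("empty taxonomy: no nodes, no root")
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise ValidationError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise ValidationError(
                    f"node {node.taxon_id} references absent parent {node.parent_id}"
                )
        # Cycle check: every parent chain must reach the root.
        for start in self.nodes:
            seen = set()
            cur = start
            while cur != self.root:
                if cur in seen:
                    raise ValidationError(f"cycle detected in taxonomy at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def parent(self, taxon_id: int) -> int:
        return self.nodes[taxon_id].parent_id

    def rank(self, taxon_id: int) -> str:
        return self.nodes[taxon_id].rank

    def name(self, taxon_id: int) -> str:
        return self.nodes[taxon_id].name or str(taxon_id)

    def lineage(self, taxon_id: int) -> list[int]:
        """Path from the taxon up to the root, taxon first."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id}")
        path = [taxon_id]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def is_ancestor_or_self(self, ancestor: int, descendant: int) -> bool:
        return ancestor in self.lineage(descendant)


def lca(tree: TaxonomyTree, taxa: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty taxon set.

    The deepest node that is an ancestor-or-self of every input taxon; a
    singleton set returns its own element.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("lca of an empty taxon set is undefined")
    common: Optional[list[int]] = None
    for t in taxa:
        lin = tree.lineage(t)  # raises KeyError on unknown taxon
        if common is None:
            common = lin
        else:
            keep = set(lin)
            common = [n for n in common if n in keep]
    assert common  # root is always shared
    return common[0]


def project_to_rank(tree: TaxonomyTree, taxon: int, rank: str) -> Optional[int]:
    """The ancestor-or-self of ``taxon`` at the requested canonical rank.

    Returns None when the lineage has no node at that rank (the assignment
    sits above it, or the lineage skips the rank).
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank label {rank!r}")
    for node_id in tree.lineage(taxon):
        if tree.rank(node_id) == rank:
            return node_id
    return None


# ---------------------------------------------------------------------------
# Loading (NCBI dmp dialect and a TSV fallback)
# ---------------------------------------------------------------------------

def _parse_dmp_line(line: str) -> list[str]:
    # NCBI dmp rows are "field\t|\tfield\t|\t...\t|\n"
    return [f.strip() for f in line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")]


def _looks_like_dmp(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t|" in line
    return False


def load_taxonomy(nodes_path: str, names_path: Optional[str] = None) -> TaxonomyTree:
    """Load a taxonomy from NCBI ``nodes.dmp``/``names.dmp`` or from TSV.

    The dmp dialect is auto-detected (pipe-and-tab delimited).  The TSV
    fallback has a header line ``taxon_id parent_id rank name`` (name
    optional) with '#' comments ignored.
    """
    nodes: dict[int, TaxNode] = {}
    if _looks_like_dmp(nodes_path):
        with open(nodes_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line)
                if len(fields) < 3:
                    raise ParseError(f"{nodes_path}, line {lineno}: expected >=3 dmp fields")
                try:
                    tid, pid = int(fields[0]), int(fields[1])
                except ValueError:
                    raise ParseError(
                        f"{nodes_path}, line {lineno}: non-numeric taxon/parent id"
                    ) from None
                nodes[tid] = TaxNode(tid, pid, fields[2])
        if names_path is not None:
            names: dict[int, str] = {}
            with open(names_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    fields = _parse_dmp_line(line)
                    if len(fields) >= 4 and fields[3] == "scientific name":
                        names[int(fields[0])] = fields[1]
            nodes = {
                tid: TaxNode(tid, n.parent_id, n.rank, names.get(tid, ""))
                for tid, n in nodes.items()
            }
    else:
        with open(nodes_path) as fh:
            header: Optional[list[str]] = None
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    for col in ("taxon_id", "parent_id", "rank"):
                        if col not in header:
                            raise ParseError(f"{nodes_path}: missing column {col!r}")
                    continue
                rec = dict(zip(header, fields))
                try:
                    tid, pid = int(rec["taxon_id"]), int(rec["parent_id"])
                except (KeyError, ValueError):
                    raise ParseError(
                        f"{nodes_path}, line {lineno}: bad taxon/parent id"
                    ) from None
                nodes[tid] = TaxNode(tid, pid, rec["rank"], rec.get("name", ""))
    return TaxonomyTree(nodes=nodes)
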