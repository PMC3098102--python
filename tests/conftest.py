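"""Shared fixtures and builders for the adjbin test suite."""

from __future__ import annotations

import hypothesis
import pytest

from adjbin import (
    BlastHit,
    GeneCatalog,
    TaxNode,
    TaxonomyTree,
    load_gene_annotations,
)

hypothesis.settings.register_profile(
    "adjbin", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("adjbin")


def catalog_from_rows(tmp_path, rows, name="annotations.tsv") -> GeneCatalog:
    """Write annotation rows as TSV and load them through the real reader.

    Each row: (genome_id, replicon_id, taxon_id, gene_id, start, end, strand,
    topology).
    """
    path = tmp_path / name
    header = "genome_id\treplicon_id\ttaxon_id\tgene_id\tstart\tend\tstrand\ttopology\n"
    body = "".join("\t".join(str(v) for v in row) + "\n" for row in rows)
    path.write_text(header + body)
    return load_gene_annotations(str(path), format="tsv")


def make_tree(spec: dict) -> TaxonomyTree:
    """Build a TaxonomyTree from {taxon_id: (parent_id, rank)} or
    {taxon_id: (parent_id, rank, name)}."""
    nodes = {}
    for tid, fields in spec.items():
        parent, rank = fields[0], fields[1]
        name = fields[2] if len(fields) > 2 else ""
        nodes[tid] = TaxNode(tid, parent, rank, name)
    return TaxonomyTree(nodes=nodes)


def make_hit(
    query="r1",
    gene="g1",
    taxon=100,
    q_lo=1,
    q_hi=300,
    strand="+",
    evalue=1e-20,
    bit=200.0,
    subject=None,
) -> BlastHit:
    q_start, q_end = (q_lo, q_hi) if strand == "+" else (q_hi, q_lo)
    return BlastHit(
        query_id=query,
        subject_id=subject or f"p_{gene}",
        percent_identity=90.0,
        align_length=(q_hi - q_lo + 1) // 3,
        evalue=evalue,
        bit_score=bit,
        q_start=q_start,
        q_end=q_end,
        s_start=1,
        s_end=(q_hi - q_lo + 1) // 3,
        subject_gene_id=gene,
        taxon_id=taxon,
    )


@pytest.fixture
def seven_rank_tree() -> TaxonomyTree:
    """Root -> Bacteria -> one full canonical lineage with two sibling species
    (8, 9) under genus 7, plus a second genus (10) with species 11 under the
    same family, and a species (21) in a different superkingdom (20)."""
    return make_tree(
        {
            1: (1, "no rank", "root"),
            2: (1, "superkingdom", "Bacteria"),
            3: (2, "phylum"),
            4: (3, "class"),
            5: (4, "order"),
            6: (5, "family"),
            7: (6, "genus"),
            8: (7, "species"),
            9: (7, "species"),
            10: (6, "genus"),
            11: (10, "species"),
            20: (1, "superkingdom", "Archaea"),
            21: (20, "species"),
        }
    )
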