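"""Classifier-ready reference formats.

Three output dialects are produced from a curated variant:

* **RDP training set** — a ``*``-delimited taxonomy tree file
  (``id*name*parentid*depth*rank``) plus a FASTA whose headers carry
  the full eight-rank lineage after a tab; consumed by the RDP
  Classifier's ``train`` command.
* **SPINGO reference** — an unwrapped FASTA whose headers carry the
  tab-separated lineage phylum→species (species last, as required for
  species-mode classification).
* **BLAST-ready FASTA** — identical to the RDP FASTA component; the
  lineage-bearing headers survive into ``makeblastdb`` databases so
  hits remain interpretable.

All writers are byte-deterministic: nodes in depth-first lexical
order, sequences in seqid order, ``\\n`` line endings.
"""

from __future__ import annotations

from typing import Sequence

from .datasets import RefSeqEntry
from .genes import CanonicalGene
from .taxonomy import Lineage, TaxonNode, TREE_RANKS, ROOT_NAME


def _lineage_string(lineage: Lineage) -> str:
    return ";".join(lineage.levels())


def _check_writable(variant: Sequence[RefSeqEntry]) -> None:
    for entry in variant:
        for name in entry.lineage.levels():
            if "\t" in name or ";" in name or "*" in name:
                raise ValueError(
                    f"{entry.seqid}: taxon name {name!r} contains a "
                    "format-reserved character")


def write_rdp(
    variant: Sequence[RefSeqEntry], tree: Sequence[TaxonNode]
) -> tuple[str, str]:
    """Render (FASTA text, taxonomy text) for RDP Classifier training.

    Every entry's lineage path must exist in *tree* (build the tree
    from the same conflict-resolved lineages).
    """
    _check_writable(variant)
    depth: dict[int, int] = {}
    paths: set[tuple[str, ...]] = set()
    node_path: dict[int, tuple[str, ...]] = {}
    for node in tree:
        if node.parent_taxid < 0:
            depth[node.taxid] = 0
            node_path[node.taxid] = (node.name,)
        else:
            depth[node.taxid] = depth[node.parent_taxid] + 1
            node_path[node.taxid] = node_path[node.parent_taxid] + (node.name,)
        paths.add(node_path[node.taxid])
    tax_lines = [
        f"{n.taxid}*{n.name}*{n.parent_taxid}*{depth[n.taxid]}*{n.rank}"
        for n in tree
    ]
    fasta_lines: list[str] = []
    for entry in sorted(variant, key=lambda e: e.seqid):
        path = entry.lineage.levels()
        if path not in paths:
            raise ValueError(
                f"{entry.seqid}: lineage {'; '.join(path)} absent from rank tree")
        fasta_lines.append(f">{entry.seqid}\t{_lineage_string(entry.lineage)}")
        seq = entry.sequence
        fasta_lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    fasta = "\n".join(fasta_lines) + ("\n" if fasta_lines else "")
    taxonomy = "\n".join(tax_lines) + ("\n" if tax_lines else "")
    return fasta, taxonomy


def _gene_from_seqid(seqid: str) -> CanonicalGene | None:
    parts = seqid.split(".")
    if len(parts) >= 3:
        try:
            return CanonicalGene(parts[-2])
        except ValueError:
            return None
    return None


def read_rdp(
    fasta_text: str,
    taxonomy_text: str,
    gene: CanonicalGene | None = None,
) -> tuple[list[RefSeqEntry], list[TaxonNode]]:
    """Inverse of :func:`write_rdp` on its image.

    The gene of each entry is recovered from its ``{acc}.{gene}.{n}``
    seqid; pass *gene* explicitly for foreign id schemes.  Malformed
    taxonomy lines, dangling parents, duplicate node ids, and FASTA
    lineages absent from the taxonomy raise ValueError.
    """
    nodes: list[TaxonNode] = []
    by_id: dict[int, TaxonNode] = {}
    for lineno, line in enumerate(taxonomy_text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("*")
        if len(fields) != 5:
            raise ValueError(
                f"taxonomy line {lineno}: expected 5 '*'-delimited fields, "
                f"got {len(fields)}: {line!r}")
        taxid, name, parent, depth_s, rank = fields
        node = TaxonNode(int(taxid), name, int(parent), rank)
        if node.taxid in by_id:
            raise ValueError(f"taxonomy line {lineno}: duplicate node id {node.taxid}")
        if node.parent_taxid >= 0 and node.parent_taxid not in by_id:
            raise ValueError(
                f"taxonomy line {lineno}: dangling parent id {node.parent_taxid}")
        expected_depth = (0 if node.parent_taxid < 0
                          else 1 + _depth_of(by_id, node.parent_taxid))
        if int(depth_s) != expected_depth:
            raise ValueError(
                f"taxonomy line {lineno}: depth {depth_s} inconsistent with parent")
        by_id[node.taxid] = node
        nodes.append(node)
    paths: set[tuple[str, ...]] = set()
    for node in nodes:
        chain = []
        cur = node
        while True:
            chain.append(cur.name)
            if cur.parent_taxid < 0:
                break
            cur = by_id[cur.parent_taxid]
        paths.add(tuple(reversed(chain)))
    entries: list[RefSeqEntry] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if "\t" not in header:
            raise ValueError(f"FASTA header lacks lineage: {header!r}")
        seqid, lin_str = header.split("\t", 1)
        levels = lin_str.split(";")
        lineage = Lineage.from_levels(levels)
        if tuple(levels) not in paths:
            raise ValueError(f"{seqid}: lineage not present in taxonomy file")
        g = gene or _gene_from_seqid(seqid)
        if g is None:
            raise ValueError(
                f"{seqid}: cannot infer gene from seqid; pass gene= explicitly")
        entries.append(RefSeqEntry(seqid, g, lineage, "".join(chunks)))

    for line in fasta_text.splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        elif line.strip():
            if header is None:
                raise ValueError("FASTA sequence data before first header")
            chunks.append(line.strip())
    flush()
    if entries and not nodes:
        raise ValueError("non-empty FASTA with empty taxonomy file")
    return entries, nodes


def _depth_of(by_id: dict[int, TaxonNode], taxid: int) -> int:
    d = 0
    cur = by_id[taxid]
    while cur.parent_taxid >= 0:
        cur = by_id[cur.parent_taxid]
        d += 1
    return d


def write_spingo(variant: Sequence[RefSeqEntry]) -> str:
    """SPINGO reference FASTA: tabbed lineage header, unwrapped sequence."""
    _check_writable(variant)
    lines: list[str] = []
    for entry in sorted(variant, key=lambda e: e.seqid):
        lin = entry.lineage
        header = "\t".join((entry.seqid, lin.phylum, lin.class_, lin.order,
                            lin.family, lin.genus, lin.species))
        lines.append(f">{header}")
        lines.append(entry.sequence)
    return "\n".join(lines) + ("\n" if lines else "")


def write_blast_fasta(
    variant: Sequence[RefSeqEntry], tree: Sequence[TaxonNode]
) -> str:
    """BLAST-ready FASTA — the RDP FASTA component, usable by makeblastdb."""
    fasta, _ = write_rdp(variant, tree)
    return fasta
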