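"""Gene-label normalization, region excision, and per-gene binning.

The mitochondrial genome of most metazoans encodes thirteen proteins
and two ribosomal RNAs.  GenBank feature labels for these genes are
notoriously heterogeneous ("COX1", "CO1", "COI", "cytochrome c oxidase
subunit I", ...), so assignment goes through a synonym table mapping
(feature kind, normalized label) to one of the fifteen canonical genes.
A default table covering the common label variants ships with the
package; a user-supplied table can extend or override it.  Features
whose labels resolve to conflicting genes, or to none, are discarded
with an audit event — a sequence that cannot be assigned unambiguously
to one gene never enters a reference dataset.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .events import CurationEvent, Reason
from .records import GeneFeature, MitoRecord


class CanonicalGene(str, enum.Enum):
    """The fifteen mitochondrial-encoded genes, by their standard abbreviations."""

    srRNA = "srRNA"
    lrRNA = "lrRNA"
    A6 = "A6"
    A8 = "A8"
    COI = "COI"
    COII = "COII"
    COIII = "COIII"
    Cytb = "Cytb"
    ND1 = "ND1"
    ND2 = "ND2"
    ND3 = "ND3"
    ND4 = "ND4"
    ND4L = "ND4L"
    ND5 = "ND5"
    ND6 = "ND6"

    def __str__(self) -> str:
        return self.value


#: The two ribosomal RNA genes; all others are protein-coding.
RRNA_GENES = frozenset({CanonicalGene.srRNA, CanonicalGene.lrRNA})
PROTEIN_GENES = frozenset(set(CanonicalGene) - RRNA_GENES)


class Unassigned(enum.Enum):
    """Sentinel results of label normalization for unusable features."""

    AMBIGUOUS = "AMBIGUOUS"
    UNKNOWN = "UNKNOWN"


AMBIGUOUS = Unassigned.AMBIGUOUS
UNKNOWN = Unassigned.UNKNOWN

_PUNCT = re.compile(r"[.,;:()]")
_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Case-fold, strip ``.,;:()`` and collapse whitespace runs."""
    return _WS.sub(" ", _PUNCT.sub("", label.casefold())).strip()


def _default_entries() -> list[tuple[str, str, CanonicalGene]]:
    G = CanonicalGene
    rrna = [
        (G.srRNA, ["srRNA", "s-rRNA", "12S", "12S rRNA", "12S ribosomal RNA",
                   "small subunit ribosomal RNA", "small ribosomal RNA subunit RNA",
                   "rrnS", "rrn12", "MT-RNR1", "RNR1",
                   "12S small subunit ribosomal RNA"]),
        (G.lrRNA, ["lrRNA", "l-rRNA", "16S", "16S rRNA", "16S ribosomal RNA",
                   "large subunit ribosomal RNA", "large ribosomal RNA subunit RNA",
                   "rrnL", "rrn16", "MT-RNR2", "RNR2",
                   "16S large subunit ribosomal RNA"]),
    ]
    cds = [
        (G.COI, ["COI", "CO1", "COX1", "COXI", "MT-CO1", "cox I",
                 "cytochrome oxidase subunit I", "cytochrome oxidase subunit 1",
                 "cytochrome c oxidase subunit I", "cytochrome c oxidase subunit 1",
                 "cytochrome oxidase I"]),
        (G.COII, ["COII", "CO2", "COX2", "COXII", "MT-CO2", "cox II",
                  "cytochrome oxidase subunit II", "cytochrome oxidase subunit 2",
                  "cytochrome c oxidase subunit II",
                  "cytochrome c oxidase subunit 2"]),
        (G.COIII, ["COIII", "CO3", "COX3", "COXIII", "MT-CO3", "cox III",
                   "cytochrome oxidase subunit III", "cytochrome oxidase subunit 3",
                   "cytochrome c oxidase subunit III",
                   "cytochrome c oxidase subunit 3"]),
        (G.Cytb, ["Cytb", "CYTB", "cyt b", "cob", "cb", "MT-CYB",
                  "cytochrome b", "cytochrome b apoenzyme",
                  "cytochrome b apoprotein"]),
        (G.A6, ["A6", "ATP6", "ATPase 6", "ATPase subunit 6", "atp6",
                "ATP synthase 6", "ATP synthase subunit 6",
                "ATP synthase F0 subunit 6", "ATPase6", "MT-ATP6"]),
        (G.A8, ["A8", "ATP8", "ATPase 8", "ATPase subunit 8", "atp8",
                "ATP synthase 8", "ATP synthase subunit 8",
                "ATP synthase F0 subunit 8", "ATPase8", "MT-ATP8"]),
    ]
    for num in ("1", "2", "3", "4", "5", "6"):
        gene = G[f"ND{num}"]
        cds.append((gene, [f"ND{num}", f"nad{num}", f"NADH{num}", f"MT-ND{num}",
                           f"NADH dehydrogenase subunit {num}",
                           f"NADH dehydrogenase subunit {num} protein"]))
    cds.append((G.ND4L, ["ND4L", "nad4L", "nad4l", "MT-ND4L",
                         "NADH dehydrogenase subunit 4L",
                         "NADH dehydrogenase subunit 4 L"]))
    out: list[tuple[str, str, CanonicalGene]] = []
    for gene, labels in rrna:
        out.extend(("rRNA", lab, gene) for lab in labels)
    for gene, labels in cds:
        out.extend(("CDS", lab, gene) for lab in labels)
    return out


@dataclass
class SynonymTable:
    """Mapping (feature kind, normalized label) → canonical gene.

    Loadable from and dumpable to 3-column tab-delimited text
    (kind, label, gene) with ``#`` comment lines.
    """

    mapping: dict[tuple[str, str], CanonicalGene]

    @classmethod
    def default(cls) -> "SynonymTable":
        table = cls(mapping={})
        for kind, label, gene in _default_entries():
            table._add(kind, label, gene)
        return table

    def _add(self, kind: str, label: str, gene: CanonicalGene) -> None:
        key = (kind, normalize_label(label))
        existing = self.mapping.get(key)
        if existing is not None and existing is not gene:
            raise ValueError(
                f"label {key!r} maps to both {existing} and {gene}"
            )
        self.mapping[key] = gene

    def lookup(self, kind: str, label: str | None) -> CanonicalGene | None:
        if label is None:
            return None
        return self.mapping.get((kind, normalize_label(label)))

    @classmethod
    def from_text(cls, text: str, base: "SynonymTable | None" = None) -> "SynonymTable":
        """Parse a 3-column TSV; entries extend/override *base* if given."""
        table = cls(mapping=dict(base.mapping) if base else {})
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"synonym table line {lineno}: expected 3 columns")
            kind, label, gene_name = parts
            if kind not in ("CDS", "rRNA"):
                raise ValueError(f"synonym table line {lineno}: bad kind {kind!r}")
            try:
                gene = CanonicalGene(gene_name)
            except ValueError:
                raise ValueError(
                    f"synonym table line {lineno}: unknown gene {gene_name!r}"
                ) from None
            # overrides replace silently; duplicates within one file must agree
            table.mapping[(kind, normalize_label(label))] = gene
        return table

    def to_text(self) -> str:
        lines = ["# kind\tlabel\tgene"]
        for (kind, label), gene in sorted(
            self.mapping.items(), key=lambda kv: (kv[0][0], kv[0][1])
        ):
            lines.append(f"{kind}\t{label}\t{gene.value}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class LabelCombination:
    """A distinct (kind, gene label, product label) triple and its frequency."""

    kind: str
    gene_label: str | None
    product_label: str | None
    count: int


def census_feature_labels(records: Sequence[MitoRecord]) -> list[LabelCombination]:
    """Count verbatim feature label combinations for human review.

    Labels are reported exactly as annotated (no normalization), sorted
    by descending count then lexically — the shape a curator scans when
    extending the synonym table.
    """
    counter: Counter[tuple[str, str | None, str | None]] = Counter()
    for rec in records:
        for feat in rec.features:
            counter[(feat.kind, feat.gene_label, feat.product_label)] += 1
    def sort_key(item):
        (kind, gene, product), count = item
        return (-count, kind, gene or "", product or "")
    return [
        LabelCombination(kind, gene, product, count)
        for (kind, gene, product), count in sorted(counter.items(), key=sort_key)
    ]


def census_to_tsv(census: Sequence[LabelCombination]) -> str:
    lines = ["kind\tgene\tproduct\tcount"]
    for row in census:
        lines.append(
            f"{row.kind}\t{row.gene_label or ''}\t{row.product_label or ''}\t{row.count}"
        )
    return "\n".join(lines) + "\n"


def normalize_gene_label(
    feature: GeneFeature, table: SynonymTable
) -> CanonicalGene | Unassigned:
    """Resolve a feature's gene/product labels to one canonical gene.

    If both labels resolve they must agree (else ``AMBIGUOUS``); if
    exactly one resolves it wins; if neither does, ``UNKNOWN``.
    """
    from_gene = table.lookup(feature.kind, feature.gene_label)
    from_product = table.lookup(feature.kind, feature.product_label)
    if from_gene is not None and from_product is not None:
        return from_gene if from_gene is from_product else AMBIGUOUS
    if from_gene is not None:
        return from_gene
    if from_product is not None:
        return from_product
    return UNKNOWN


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


def excise_region(record: MitoRecord, feature: GeneFeature) -> str:
    """Cut the annotated gene region out of the record sequence.

    Span substrings are concatenated in genomic order; reverse-strand
    features return the reverse complement of the concatenation, so the
    result always reads in the gene's sense orientation.
    """
    n = len(record.sequence)
    for span in feature.spans:
        if span.end > n:
            raise ValueError(
                f"{record.accession}: span [{span.start},{span.end}) "
                f"outside sequence of length {n}"
            )
    raw = "".join(record.sequence[s.start:s.end] for s in feature.spans)
    return reverse_complement(raw) if feature.strand == "reverse" else raw


def partition_by_gene(
    records: Sequence[MitoRecord],
    table: SynonymTable | None = None,
) -> tuple[dict[CanonicalGene, list[tuple[str, str]]], list[CurationEvent]]:
    """Assign, excise, and partition features into per-gene bins.

    Returns a bin for every canonical gene (empty bins included) holding
    ``(entry id, excised sequence)`` pairs, plus events for features
    that were ambiguous, unknown, or failed excision.  Entry ids are
    ``{accession}.{gene}.{ordinal}`` with the ordinal counting that
    gene's features within the record, so duplicated annotations stay
    distinguishable.
    """
    if table is None:
        table = SynonymTable.default()
    bins: dict[CanonicalGene, list[tuple[str, str]]] = {
        gene: [] for gene in CanonicalGene
    }
    events: list[CurationEvent] = []
    for rec in records:
        per_gene_ordinal: Counter[CanonicalGene] = Counter()
        for feat in rec.features:
            assigned = normalize_gene_label(feat, table)
            if assigned is AMBIGUOUS:
                events.append(CurationEvent(
                    rec.accession, "gene_assignment", Reason.AMBIGUOUS_GENE,
                    f"gene={feat.gene_label!r} product={feat.product_label!r}"))
                continue
            if assigned is UNKNOWN:
                events.append(CurationEvent(
                    rec.accession, "gene_assignment", Reason.UNKNOWN_GENE,
                    f"gene={feat.gene_label!r} product={feat.product_label!r}"))
                continue
            try:
                seq = excise_region(rec, feat)
            except ValueError as exc:
                events.append(CurationEvent(
                    rec.accession, "excision", Reason.EXCISION_ERROR, str(exc)))
                continue
            per_gene_ordinal[assigned] += 1
            entry_id = f"{rec.accession}.{assigned.value}.{per_gene_ordinal[assigned]}"
            bins[assigned].append((entry_id, seq))
    return bins, events


def accession_of(entry_id: str) -> str:
    """Recover the source accession from a ``{acc}.{gene}.{n}`` entry id."""
    return entry_id.rsplit(".", 2)[0]
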