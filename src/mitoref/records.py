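"""Annotated nucleotide records: flatfile parsing and pre-filters.

The pipeline ingests multi-record GenBank flatfiles (plain text).  Only
CDS and rRNA features are retained — they are the only feature kinds
that can carry one of the fifteen mitochondrial genes.  Coordinates are
converted exactly once, at parse time, from the flatfile's 1-based
inclusive convention to 0-based half-open spans; everything downstream
assumes Python slicing semantics.

Two pre-filters narrow the stream before gene assignment:

* :func:`filter_mitochondrial` keeps records that either carry an
  ``organelle=mitochondrion`` source qualifier or whose definition line
  matches a mitochondrion keyword (nuclear-encoded mitochondrial genes
  have no organelle qualifier but are named in the definition);
* :func:`filter_metazoa` keeps records whose taxonomic ancestry
  contains the node name ``Metazoa``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .events import CurationEvent, Reason

#: IUPAC nucleotide one-letter codes (T and U both accepted on ingest).
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

#: Default definition-line keywords marking mitochondria-related records.
DEFAULT_MITO_KEYWORDS = ("mitochondri", "mitogenome")


@dataclass(frozen=True)
class LocationSpan:
    """0-based half-open interval on the record sequence."""

    start: int
    end: int
    strand: str = "forward"  # "forward" | "reverse"
    partial5: bool = False
    partial3: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneFeature:
    """A CDS or rRNA feature with its raw gene/product labels."""

    kind: str  # "CDS" | "rRNA"
    spans: list[LocationSpan]
    gene_label: str | None = None
    product_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "rRNA"):
            raise ValueError(f"feature kind must be CDS or rRNA, got {self.kind!r}")
        if not self.spans:
            raise ValueError("feature has no spans")

    @property
    def strand(self) -> str:
        return self.spans[0].strand

    @property
    def span_length(self) -> int:
        return sum(len(s) for s in self.spans)


@dataclass
class MitoRecord:
    """One annotated nucleotide record."""

    accession: str
    sequence: str
    version: str | None = None
    definition: str = ""
    organism: str = ""
    taxid: int | None = None
    raw_lineage: list[str] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    source_qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for feat in self.features:
            for span in feat.spans:
                if span.end > len(self.sequence):
                    raise ValueError(
                        f"{self.accession}: span [{span.start},{span.end}) "
                        f"outside sequence of length {len(self.sequence)}"
                    )


def _iter_flatfile_chunks(stream: TextIO) -> Iterable[tuple[str, bool]]:
    """Yield (record text, terminated) chunks split on '//' lines."""
    buf: list[str] = []
    for line in stream:
        buf.append(line)
        if line.rstrip() == "//":
            yield "".join(buf), True
            buf = []
    if any(ln.strip() for ln in buf):
        yield "".join(buf), False


def _convert_feature(bio_feature) -> GeneFeature:
    loc = bio_feature.location
    parts = list(loc.parts) if isinstance(loc, CompoundLocation) else [loc]
    strand = "reverse" if (loc.strand is not None and loc.strand < 0) else "forward"
    spans = []
    for p in parts:
        partial5 = "<" in str(p.start)
        partial3 = ">" in str(p.end)
        spans.append(
            LocationSpan(int(p.start), int(p.end), strand, partial5, partial3)
        )
    # complement(join(...)) arrives in transcription order; store in
    # ascending genomic order so excision can slice then reverse-complement.
    spans.sort(key=lambda s: s.start)
    quals = bio_feature.qualifiers
    return GeneFeature(
        kind=bio_feature.type,
        spans=spans,
        gene_label=quals.get("gene", [None])[0],
        product_label=quals.get("product", [None])[0],
    )


def _convert_record(rec) -> MitoRecord:
    sequence = str(rec.seq).upper()
    bad = set(sequence) - IUPAC_NT
    if bad:
        raise _AlphabetError(sorted(bad))
    source_quals: dict[str, str] = {}
    taxid: int | None = None
    features: list[GeneFeature] = []
    for f in rec.features:
        if f.type == "source":
            for key, vals in f.qualifiers.items():
                if vals:
                    source_quals[key] = vals[0]
            for xref in f.qualifiers.get("db_xref", []):
                if xref.startswith("taxon:"):
                    taxid = int(xref.split(":", 1)[1])
        elif f.type in ("CDS", "rRNA"):
            feat = _convert_feature(f)
            for span in feat.spans:
                if span.end > len(sequence):
                    raise ValueError(
                        f"feature span [{span.start},{span.end}) outside sequence"
                    )
            features.append(feat)
    accession = rec.id.split(".")[0] if rec.id else rec.name
    return MitoRecord(
        accession=accession,
        sequence=sequence,
        version=rec.id if "." in (rec.id or "") else None,
        definition=rec.description or "",
        organism=rec.annotations.get("organism", ""),
        taxid=taxid,
        raw_lineage=list(rec.annotations.get("taxonomy", [])),
        features=features,
        source_qualifiers=source_quals,
    )


class _AlphabetError(ValueError):
    def __init__(self, letters: list[str]):
        super().__init__(f"non-IUPAC letters {letters}")
        self.letters = letters


def parse_genbank_flatfile(
    stream: TextIO | str,
) -> tuple[list[MitoRecord], list[CurationEvent]]:
    """Parse a multi-record GenBank flatfile.

    Malformed records (missing LOCUS/ACCESSION/ORIGIN, truncated final
    record, non-IUPAC letters) produce a record-level event and parsing
    continues with the next record.

    Returns
    -------
    (records, events)
        Parsed records in file order, and one event per rejected record.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[MitoRecord] = []
    events: list[CurationEvent] = []
    seen: set[str] = set()
    for idx, (chunk, terminated) in enumerate(_iter_flatfile_chunks(stream)):
        label = _chunk_label(chunk, idx)
        if not terminated:
            events.append(
                CurationEvent(label, "parse", Reason.PARSE_ERROR,
                              "truncated final record (missing // terminator)")
            )
            continue
        try:
            bio = SeqIO.read(io.StringIO(chunk), "genbank")
            rec = _convert_record(bio)
        except _AlphabetError as exc:
            events.append(CurationEvent(label, "parse", Reason.BAD_ALPHABET, str(exc)))
            continue
        except Exception as exc:  # malformed flatfile chunk
            events.append(CurationEvent(label, "parse", Reason.PARSE_ERROR, str(exc)))
            continue
        if rec.accession in seen:
            events.append(
                CurationEvent(rec.accession, "parse", Reason.PARSE_ERROR,
                              "duplicate accession in input stream")
            )
            continue
        seen.add(rec.accession)
        records.append(rec)
    return records, events


def _chunk_label(chunk: str, idx: int) -> str:
    for line in chunk.splitlines():
        if line.startswith("ACCESSION"):
            parts = line.split()
            if len(parts) > 1:
                return parts[1]
        if line.startswith("LOCUS"):
            parts = line.split()
            if len(parts) > 1:
                return parts[1]
    return f"record#{idx}"


def filter_mitochondrial(
    records: Sequence[MitoRecord],
    keywords: Sequence[str] = DEFAULT_MITO_KEYWORDS,
) -> tuple[list[MitoRecord], list[CurationEvent]]:
    """Keep records that are mitochondria-related.

    A record is kept iff its source feature carries
    ``organelle=mitochondrion`` (any mitochondrion subtype) or its
    definition line contains one of *keywords* case-insensitively.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    kept: list[MitoRecord] = []
    events: list[CurationEvent] = []
    for rec in records:
        organelle = rec.source_qualifiers.get("organelle", "")
        is_mito = organelle.startswith("mitochondrion") or any(
            k in rec.definition.lower() for k in lowered
        )
        if is_mito:
            kept.append(rec)
        else:
            events.append(
                CurationEvent(rec.accession, "mito_filter", Reason.NOT_MITO,
                              f"definition={rec.definition[:60]!r}")
            )
    return kept, events


def filter_metazoa(
    records: Sequence[MitoRecord],
    lineage_index: Mapping[int, Sequence[str]] | None = None,
) -> tuple[list[MitoRecord], list[CurationEvent]]:
    """Keep records whose ancestry contains the node name ``Metazoa``.

    Ancestry is resolved through *lineage_index* (taxid → ancestor
    names, e.g. :meth:`mitoref.taxonomy.TaxdumpIndex.ancestor_names`)
    when the record has a resolvable taxid, otherwise through the
    record's own lineage annotation.  Matching is by exact,
    case-sensitive node name.
    """
    kept: list[MitoRecord] = []
    events: list[CurationEvent] = []
    for rec in records:
        ancestors: Sequence[str] | None = None
        if lineage_index is not None and rec.taxid is not None:
            try:
                ancestors = lineage_index[rec.taxid]
            except KeyError:
                ancestors = None
        if ancestors is None and rec.raw_lineage:
            ancestors = rec.raw_lineage
        if ancestors is None:
            events.append(
                CurationEvent(rec.accession, "metazoa_filter",
                              Reason.TAXID_UNRESOLVED,
                              f"taxid={rec.taxid}")
            )
        elif "Metazoa" in ancestors:
            kept.append(rec)
        else:
            events.append(
                CurationEvent(rec.accession, "metazoa_filter", Reason.NOT_METAZOA,
                              "; ".join(ancestors[:4]))
            )
    return kept, events


def write_fasta(entries: Iterable[tuple[str, str]], wrap: int = 60) -> str:
    """Render (seqid, sequence) pairs as FASTA text, wrapped at *wrap* columns."""
    out: list[str] = []
    for seqid, seq in entries:
        out.append(f">{seqid}")
        if wrap:
            out.extend(seq[i:i + wrap] for i in range(0, len(seq), wrap))
        else:
            out.append(seq)
    return "\n".join(out) + "\n" if out else ""


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (full header, sequence) pairs."""
    return [
        (rec.description, str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
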