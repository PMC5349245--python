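"""Length filtering, dereplication, and coverage statistics.

Two dataset variants are built per gene:

* **UNIQUE** — one representative per distinct haplotype (exact,
  case-folded sequence identity) within each species; the variant used
  for the mislabel screen.
* **LONGEST** — a single sequence per species, the longest one (ties
  broken by smallest sequence id); the variant used for per-phylum
  coverage statistics.

Before dereplication, per-gene length windows remove extremely short or
long annotations, which are disproportionately mis-annotated and are
known to derail naive-Bayes taxonomic assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import CurationEvent, Reason
from .genes import CanonicalGene
from .taxonomy import Lineage

#: Default per-gene (min, max) retained lengths in nt, bounds inclusive.
DEFAULT_LENGTH_WINDOWS: dict[CanonicalGene, tuple[int, int]] = {
    CanonicalGene.srRNA: (200, 2000),
    CanonicalGene.lrRNA: (100, 2500),
    CanonicalGene.A6: (100, 1000),
    CanonicalGene.A8: (100, 500),
    CanonicalGene.COI: (100, 2000),
    CanonicalGene.COII: (100, 1500),
    CanonicalGene.COIII: (100, 1300),
    CanonicalGene.Cytb: (100, 1500),
    CanonicalGene.ND1: (50, 1200),
    CanonicalGene.ND2: (150, 1500),
    CanonicalGene.ND3: (100, 600),
    CanonicalGene.ND4: (150, 2000),
    CanonicalGene.ND4L: (100, 700),
    CanonicalGene.ND5: (150, 2000),
    CanonicalGene.ND6: (150, 1500),
}


@dataclass(frozen=True)
class LengthPolicy:
    """Per-gene retained length windows, inclusive on both ends."""

    windows: Mapping[CanonicalGene, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WINDOWS)
    )

    def __post_init__(self) -> None:
        for gene in CanonicalGene:
            lo, hi = self.windows[gene]
            if not lo < hi:
                raise ValueError(f"{gene}: window min {lo} must be < max {hi}")

    def window(self, gene: CanonicalGene) -> tuple[int, int]:
        return self.windows[gene]


@dataclass(frozen=True)
class RefSeqEntry:
    """A curated per-gene reference sequence with its lineage."""

    seqid: str
    gene: CanonicalGene
    lineage: Lineage
    sequence: str

    @property
    def species(self) -> str:
        return self.lineage.species

    @property
    def phylum(self) -> str:
        return self.lineage.phylum


def _sort_key(entry: RefSeqEntry) -> tuple[str, str, str]:
    return (entry.gene.value, entry.species, entry.seqid)


def apply_length_filter(
    entries: Sequence[RefSeqEntry],
    policy: LengthPolicy | None = None,
) -> tuple[list[RefSeqEntry], list[CurationEvent]]:
    """Keep entries whose length lies inside their gene's window (inclusive)."""
    if policy is None:
        policy = LengthPolicy()
    kept: list[RefSeqEntry] = []
    events: list[CurationEvent] = []
    for entry in entries:
        lo, hi = policy.window(entry.gene)
        n = len(entry.sequence)
        if lo <= n <= hi:
            kept.append(entry)
        else:
            events.append(CurationEvent(
                entry.seqid, "length_filter", Reason.LENGTH_OUT_OF_RANGE,
                f"{entry.gene.value} length {n} outside [{lo}, {hi}]"))
    return kept, events


def collapse_unique(entries: Sequence[RefSeqEntry]) -> list[RefSeqEntry]:
    """UNIQUE variant: one representative per distinct haplotype per species.

    Haplotype identity is exact string equality after case-folding;
    ambiguity codes are not expanded.  The representative of each
    haplotype is the carrier with the smallest sequence id.  Output is
    sorted by (gene, species, seqid), so the result is independent of
    input order.
    """
    best: dict[tuple[CanonicalGene, str, str], RefSeqEntry] = {}
    for entry in entries:
        key = (entry.gene, entry.species, entry.sequence.casefold())
        cur = best.get(key)
        if cur is None or entry.seqid < cur.seqid:
            best[key] = entry
    return sorted(best.values(), key=_sort_key)


def select_longest(entries: Sequence[RefSeqEntry]) -> list[RefSeqEntry]:
    """LONGEST variant: the single longest sequence per (gene, species).

    Length ties are broken by the smallest sequence id.  Output sorted
    by (gene, species, seqid).
    """
    best: dict[tuple[CanonicalGene, str], RefSeqEntry] = {}
    for entry in entries:
        key = (entry.gene, entry.species)
        cur = best.get(key)
        if (cur is None
                or len(entry.sequence) > len(cur.sequence)
                or (len(entry.sequence) == len(cur.sequence)
                    and entry.seqid < cur.seqid)):
            best[key] = entry
    return sorted(best.values(), key=_sort_key)


def group_by_gene(
    entries: Sequence[RefSeqEntry],
) -> dict[CanonicalGene, list[RefSeqEntry]]:
    """Split a variant into per-gene lists (every gene present, possibly empty)."""
    bins: dict[CanonicalGene, list[RefSeqEntry]] = {g: [] for g in CanonicalGene}
    for entry in entries:
        bins[entry.gene].append(entry)
    return bins


def coverage_percentages(
    variant: Sequence[RefSeqEntry],
    described_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-(phylum, gene) species coverage against described species counts.

    ``100 × (#species in the variant with that gene) / (#described
    species of the phylum)``, rounded to 2 decimals.  Intended for the
    LONGEST variant (one sequence per species).  May exceed 100 when
    the dataset distinguishes more species than the census describes.
    Phyla present in the data but absent from *described_counts* get a
    missing percentage (NaN) in every gene column.
    """
    species_sets: dict[tuple[str, CanonicalGene], set[str]] = {}
    phyla = sorted({e.phylum for e in variant})
    for entry in variant:
        species_sets.setdefault((entry.phylum, entry.gene), set()).add(entry.species)
    rows = {}
    for phylum in phyla:
        denom = described_counts.get(phylum)
        row = {}
        for gene in CanonicalGene:
            n = len(species_sets.get((phylum, gene), ()))
            if denom is None:
                row[gene.value] = float("nan")
            else:
                if denom <= 0:
                    raise ValueError(f"described count for {phylum} must be positive")
                row[gene.value] = round(100.0 * n / denom, 2)
        rows[phylum] = row
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[g.value for g in CanonicalGene])
    table.index.name = "phylum"
    return table


def variant_counts(variant: Sequence[RefSeqEntry]) -> dict[str, int]:
    """Per-gene sequence counts of a variant (report-table shape)."""
    counts = {g.value: 0 for g in CanonicalGene}
    for entry in variant:
        counts[entry.gene.value] += 1
    return counts
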