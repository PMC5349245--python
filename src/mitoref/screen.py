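"""Cluster-based screen for taxonomically mislabelled reference sequences.

Within the typical range of intra-specific variation for mitochondrial
genes (≥99% identity), sequences falling into one cluster should carry
the same higher-level taxonomic labels.  Each gene's UNIQUE variant is
therefore clustered greedily at high identity and any cluster holding
two or more distinct phyla, classes, or orders is flagged for expert
review.  Deciding *which* member of a flagged cluster is mislabelled
requires phylogenetic judgement, so removal is driven by a supplied
adjudication list rather than decided automatically.

Identity definition
-------------------
Sequences of one gene bin are already orientation-normalised, so only
the forward strand is compared.  The shorter sequence is aligned
semi-globally against the longer one (terminal gaps in the longer
sequence are free, i.e. the shorter sequence may match any substring),
minimising unit-cost edit distance *d*; identity is ``1 − d /
len(shorter)``.  IUPAC ambiguity letters match only when literally
equal.  This is deterministic and symmetric, and for the near-identical
pairs the screen cares about it coincides with the fraction of matching
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .datasets import RefSeqEntry
from .events import CurationEvent, Reason
from .genes import CanonicalGene
from .taxonomy import is_placeholder

#: Taxonomic levels screened for label mixing.
SCREEN_LEVELS = ("phylum", "class", "order")


@dataclass(frozen=True)
class IdentityParams:
    """Clustering parameters: identity threshold and prescreen word size."""

    threshold: float = 0.99
    prescreen: bool = True
    prescreen_k: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.prescreen_k < 2:
            raise ValueError("prescreen word size must be ≥ 2")


def _semiglobal_distance(query: str, target: str) -> int:
    """Minimal edit distance of *query* to any substring of *target*."""
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


def pairwise_identity(a: str, b: str, params: IdentityParams | None = None) -> float:
    """Semi-global identity of two sequences (see module docstring).

    Symmetric in its arguments; 1.0 for identical strings.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a == b:
        return 1.0
    if len(a) > len(b):
        a, b = b, a
    d = _semiglobal_distance(a, b)
    if len(a) == len(b):  # alignment direction can matter; keep it symmetric
        d = min(d, _semiglobal_distance(b, a))
    return 1.0 - d / len(a)


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def min_shared_words(query_length: int, params: IdentityParams) -> int:
    """Word-count lower bound used by the clustering prescreen.

    If identity ≥ t then the edit distance d ≤ (1−t)·|query|, and each
    of the d edits can disturb at most k of the query's overlapping
    k-words; every undisturbed word occurs verbatim in the target.  So
    at least (|query|−k+1) − k·⌊(1−t)·|query|⌋ query word positions
    must have their word present in the target — fewer shared words
    proves identity < t.  A bound ≤ 0 means the prescreen cannot
    exclude anything for this query length.
    """
    k = params.prescreen_k
    m = query_length
    if m < k:
        return 0
    d_max = int((1.0 - params.threshold) * m)
    return (m - k + 1) - k * d_max


@dataclass
class Cluster:
    """One greedy cluster: centroid entry plus members (centroid first)."""

    gene: CanonicalGene
    centroid: str
    members: list[RefSeqEntry] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.seqid for m in self.members]

    def labels(self, level: str) -> set[str]:
        """Distinct non-placeholder labels of the members at *level*."""
        out = set()
        for m in self.members:
            name = getattr(m.lineage, "class_" if level == "class" else level)
            if not is_placeholder(name):
                out.add(name)
        return out


def greedy_cluster(
    entries: Sequence[RefSeqEntry], params: IdentityParams | None = None
) -> list[Cluster]:
    """Greedy centroid clustering of one gene's entries.

    Entries are processed in decreasing length order (ties by seqid);
    each joins the first existing centroid — in centroid creation order
    — whose identity to it reaches the threshold, else founds a new
    cluster.  Because entries arrive longest-first, every member is no
    longer than its centroid.  Deterministic for a given input set.
    """
    if params is None:
        params = IdentityParams()
    genes = {e.gene for e in entries}
    if len(genes) > 1:
        raise ValueError(f"entries span multiple genes: {sorted(g.value for g in genes)}")
    ordered = sorted(entries, key=lambda e: (-len(e.sequence), e.seqid))
    clusters: list[Cluster] = []
    # inverted word index: k-mer -> centroid indices containing it (each once)
    word_index: dict[str, list[int]] = {}
    k = params.prescreen_k
    for entry in ordered:
        seq = entry.sequence
        required = min_shared_words(len(seq), params) if params.prescreen else 0
        if required > 0:
            shared: dict[int, int] = {}
            for i in range(len(seq) - k + 1):
                for ci in word_index.get(seq[i:i + k], ()):
                    shared[ci] = shared.get(ci, 0) + 1
            candidates = sorted(ci for ci, n in shared.items() if n >= required)
        else:
            candidates = range(len(clusters))
        joined = False
        for ci in candidates:
            cluster = clusters[ci]
            if (
                pairwise_identity(seq, cluster.members[0].sequence, params)
                >= params.threshold
            ):
                cluster.members.append(entry)
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(Cluster(entry.gene, entry.seqid, [entry]))
            for word in _kmer_set(seq, k):
                word_index.setdefault(word, []).append(ci)
    return clusters


@dataclass(frozen=True)
class FlaggedCluster:
    """A cluster holding more than one higher taxon at some level."""

    gene: CanonicalGene
    centroid: str
    member_ids: tuple[str, ...]
    mixed_levels: tuple[str, ...]
    labels: Mapping[str, tuple[str, ...]]  # level -> sorted distinct labels


@dataclass
class FlagReport:
    """Per-gene counts of mixed clusters and the flagged clusters themselves."""

    counts: dict[CanonicalGene, dict[str, int]]
    flagged: list[FlaggedCluster]

    def flagged_ids(self) -> set[str]:
        return {sid for fc in self.flagged for sid in fc.member_ids}

    def to_tsv(self, removed: Mapping[CanonicalGene, int] | None = None) -> str:
        """Report-table layout: gene, mixed-cluster counts per level, removals."""
        lines = ["gene\tphylum_mixed\tclass_mixed\torder_mixed\tremoved"]
        for gene in CanonicalGene:
            row = self.counts.get(gene, {lv: 0 for lv in SCREEN_LEVELS})
            n_removed = (removed or {}).get(gene, 0)
            lines.append(
                f"{gene.value}\t{row['phylum']}\t{row['class']}\t"
                f"{row['order']}\t{n_removed}"
            )
        return "\n".join(lines) + "\n"


def flag_mixed_clusters(clusters: Sequence[Cluster]) -> FlagReport:
    """Flag clusters with ≥2 distinct non-placeholder labels at any level.

    Levels are counted independently: a cluster mixing two phyla is
    also counted at class and order when the labels differ there too.
    Placeholder labels (synthesised for missing ranks) never count
    toward mixing.
    """
    counts: dict[CanonicalGene, dict[str, int]] = {
        g: {lv: 0 for lv in SCREEN_LEVELS} for g in CanonicalGene
    }
    flagged: list[FlaggedCluster] = []
    for cluster in clusters:
        mixed_levels = []
        labels = {}
        for level in SCREEN_LEVELS:
            distinct = cluster.labels(level)
            labels[level] = tuple(sorted(distinct))
            if len(distinct) >= 2:
                mixed_levels.append(level)
                counts[cluster.gene][level] += 1
        if mixed_levels:
            flagged.append(FlaggedCluster(
                gene=cluster.gene,
                centroid=cluster.centroid,
                member_ids=tuple(cluster.member_ids),
                mixed_levels=tuple(mixed_levels),
                labels=labels,
            ))
    return FlagReport(counts=counts, flagged=flagged)


def flag_events(report: FlagReport) -> list[CurationEvent]:
    """One MISLABEL_FLAGGED event per member of each flagged cluster."""
    events = []
    for fc in report.flagged:
        for sid in fc.member_ids:
            events.append(CurationEvent(
                sid, "mislabel_screen", Reason.MISLABEL_FLAGGED,
                f"{fc.gene.value} cluster {fc.centroid} mixes "
                + "; ".join(f"{lv}={'|'.join(fc.labels[lv])}"
                            for lv in fc.mixed_levels)))
    return events


def read_removal_list(text: str) -> list[str]:
    """Parse an adjudication list: one seqid per line, ``#`` comments."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def apply_adjudication(
    variant: Sequence[RefSeqEntry],
    removals: Iterable[str],
    report: FlagReport,
) -> tuple[list[RefSeqEntry], list[CurationEvent]]:
    """Remove adjudicated mislabels from a variant.

    Every id in *removals* must name a member of a flagged cluster;
    unknown or unflagged ids are rejected.  Entries that were flagged
    but not adjudicated as mislabelled are retained.
    """
    removal_set = set(removals)
    known = {e.seqid for e in variant}
    unknown = sorted(removal_set - known)
    if unknown:
        raise ValueError(f"removal ids not present in variant: {unknown}")
    unflagged = sorted(removal_set - report.flagged_ids())
    if unflagged:
        raise ValueError(f"removal ids were never flagged: {unflagged}")
    kept = [e for e in variant if e.seqid not in removal_set]
    events = [
        CurationEvent(sid, "mislabel_screen", Reason.MISLABEL_REMOVED,
                      "adjudicated mislabel")
        for sid in sorted(removal_set)
    ]
    return kept, events
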