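"""End-to-end curation: flatfile in, classifier-ready datasets out.

Stage order::

    parse → mito filter → metazoan filter → gene assignment/excision →
    lineage resolution + QC → name-conflict resolution → length filter →
    dereplication (UNIQUE, LONGEST) → mislabel screen (on UNIQUE) →
    optional adjudicated removal → format writers + reports

:func:`curate` is the in-memory engine (texts in, result object out);
:func:`run_pipeline` wraps it with file I/O and writes every artifact
and report to an output directory.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import datasets, screen, taxonomy, writers
from .events import CurationEvent, Reason, events_to_tsv
from .genes import (CanonicalGene, SynonymTable, accession_of,
                    partition_by_gene)
from .records import (DEFAULT_MITO_KEYWORDS, filter_metazoa,
                      filter_mitochondrial, parse_genbank_flatfile,
                      write_fasta)
from .taxonomy import (Lineage, QCPolicy, TaxdumpIndex, build_rank_tree,
                       qc_lineage, rename_map_to_tsv, resolve_lineage,
                       resolve_name_conflicts)


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the published parameters."""

    input_path: Path | None = None
    nodes_path: Path | None = None
    names_path: Path | None = None
    synonyms_path: Path | None = None
    removals_path: Path | None = None
    described_counts_path: Path | None = None
    outdir: Path = Path("mitoref_out")
    variant: str = "both"  # UNIQUE | LONGEST | both
    threshold: float = 0.99
    mito_keywords: tuple[str, ...] = DEFAULT_MITO_KEYWORDS
    qc_policy: QCPolicy = field(default_factory=QCPolicy)
    length_policy: datasets.LengthPolicy = field(
        default_factory=datasets.LengthPolicy)
    run_screen: bool = True

    _KEYS = ("input", "nodes", "names", "synonyms", "removals",
             "described_counts", "outdir", "variant", "threshold",
             "mito_keywords", "run_screen")

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        """Parse a simple ``key = value`` config; unknown keys are rejected."""
        cfg = cls()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls._KEYS:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            if key in ("input", "nodes", "names", "synonyms", "removals",
                       "described_counts", "outdir"):
                setattr(cfg, f"{key}_path" if key != "outdir" else "outdir",
                        Path(value))
            elif key == "variant":
                if value not in ("UNIQUE", "LONGEST", "both"):
                    raise ValueError(f"config line {lineno}: bad variant {value!r}")
                cfg.variant = value
            elif key == "threshold":
                cfg.threshold = float(value)
            elif key == "mito_keywords":
                cfg.mito_keywords = tuple(
                    k.strip() for k in value.split(",") if k.strip())
            elif key == "run_screen":
                cfg.run_screen = value.lower() in ("1", "true", "yes")
        return cfg


@dataclass
class PipelineResult:
    """Everything one curation run produces, in memory."""

    n_parsed: int
    events: list[CurationEvent]
    unique: list[datasets.RefSeqEntry]
    longest: list[datasets.RefSeqEntry]
    tree: list[taxonomy.TaxonNode]
    flag_report: screen.FlagReport | None
    rename_map: taxonomy.RenameMap
    removed_per_gene: dict[CanonicalGene, int]
    stage_counts: dict[str, int]

    def summary_tsv(self) -> str:
        lines = ["section\tkey\tvalue"]
        for stage, count in self.stage_counts.items():
            lines.append(f"stage\t{stage}\t{count}")
        for name, variant in (("UNIQUE", self.unique), ("LONGEST", self.longest)):
            counts = datasets.variant_counts(variant)
            for gene in CanonicalGene:
                lines.append(f"{name}\t{gene.value}\t{counts[gene.value]}")
        return "\n".join(lines) + "\n"


def curate(
    flatfile_text: str,
    nodes_text: str,
    names_text: str,
    synonyms: SynonymTable | None = None,
    mito_keywords: Sequence[str] = DEFAULT_MITO_KEYWORDS,
    qc_policy: QCPolicy | None = None,
    length_policy: datasets.LengthPolicy | None = None,
    identity_params: screen.IdentityParams | None = None,
    removals: Sequence[str] = (),
    run_screen: bool = True,
) -> PipelineResult:
    """Run the full curation pipeline on in-memory inputs."""
    events: list[CurationEvent] = []
    stage_counts: dict[str, int] = {}

    records, parse_events = parse_genbank_flatfile(flatfile_text)
    events.extend(parse_events)
    stage_counts["parsed"] = len(records)

    index = TaxdumpIndex.from_taxdump(nodes_text, names_text)
    records, ev = filter_mitochondrial(records, mito_keywords)
    events.extend(ev)
    stage_counts["mitochondrial"] = len(records)
    records, ev = filter_metazoa(records, index)
    events.extend(ev)
    stage_counts["metazoan"] = len(records)

    bins, ev = partition_by_gene(records, synonyms)
    events.extend(ev)
    stage_counts["gene_assigned_entries"] = sum(len(b) for b in bins.values())

    # lineage resolution + QC, per record
    lineage_by_acc: dict[str, Lineage] = {}
    for rec in records:
        if rec.taxid is None:
            events.append(CurationEvent(rec.accession, "lineage",
                                        Reason.TAXID_UNRESOLVED, "no taxid"))
            continue
        try:
            lineage = resolve_lineage(rec.taxid, index)
        except LookupError as exc:
            events.append(CurationEvent(rec.accession, "lineage",
                                        Reason.TAXID_UNRESOLVED, str(exc)))
            continue
        verdict = qc_lineage(lineage, qc_policy, subject=rec.accession)
        if verdict is not None:
            events.append(verdict)
            continue
        lineage_by_acc[rec.accession] = lineage
    stage_counts["lineage_qc_passed"] = len(lineage_by_acc)

    # conflict resolution over the distinct retained lineages
    distinct = sorted({lin.levels() for lin in lineage_by_acc.values()})
    resolved, rename_map = resolve_name_conflicts(
        [Lineage.from_levels(levels) for levels in distinct])
    lineage_lookup = dict(zip(distinct, resolved))
    lineage_by_acc = {
        acc: lineage_lookup[lin.levels()]
        for acc, lin in lineage_by_acc.items()
    }

    entries: list[datasets.RefSeqEntry] = []
    for gene in CanonicalGene:
        for entry_id, seq in bins[gene]:
            lineage = lineage_by_acc.get(accession_of(entry_id))
            if lineage is not None:
                entries.append(
                    datasets.RefSeqEntry(entry_id, gene, lineage, seq))

    entries, ev = datasets.apply_length_filter(entries, length_policy)
    events.extend(ev)
    stage_counts["length_passed_entries"] = len(entries)

    unique = datasets.collapse_unique(entries)
    stage_counts["unique_entries"] = len(unique)

    flag_report: screen.FlagReport | None = None
    removed_per_gene: dict[CanonicalGene, int] = {g: 0 for g in CanonicalGene}
    if run_screen:
        clusters: list[screen.Cluster] = []
        for gene, gene_entries in datasets.group_by_gene(unique).items():
            if gene_entries:
                clusters.extend(screen.greedy_cluster(gene_entries,
                                                      identity_params))
        flag_report = screen.flag_mixed_clusters(clusters)
        events.extend(screen.flag_events(flag_report))
        if removals:
            unique, ev = screen.apply_adjudication(unique, removals, flag_report)
            events.extend(ev)
            for e in ev:
                gene = CanonicalGene(e.subject.rsplit(".", 2)[1])
                removed_per_gene[gene] += 1
    elif removals:
        raise ValueError("adjudicated removals require the screen to run")

    longest = datasets.select_longest(unique)
    stage_counts["longest_entries"] = len(longest)

    tree = build_rank_tree(
        sorted({e.lineage for e in unique}, key=lambda l: l.levels()))
    return PipelineResult(
        n_parsed=stage_counts["parsed"], events=events, unique=unique,
        longest=longest, tree=tree, flag_report=flag_report,
        rename_map=rename_map, removed_per_gene=removed_per_gene,
        stage_counts=stage_counts)


def _read_described_counts(text: str) -> dict[str, int]:
    counts = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("phylum\t"):
            continue
        phylum, value = line.split("\t")
        counts[phylum] = int(value)
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: read inputs, curate, write all artifacts."""
    if config.input_path is None or config.nodes_path is None \
            or config.names_path is None:
        raise ValueError("input, nodes and names paths are required")
    flatfile = Path(config.input_path).read_text()
    nodes_text = Path(config.nodes_path).read_text()
    names_text = Path(config.names_path).read_text()
    synonyms = None
    if config.synonyms_path is not None:
        synonyms = SynonymTable.from_text(
            Path(config.synonyms_path).read_text(), base=SynonymTable.default())
    removals: list[str] = []
    if config.removals_path is not None:
        removals = screen.read_removal_list(Path(config.removals_path).read_text())

    result = curate(
        flatfile, nodes_text, names_text, synonyms=synonyms,
        mito_keywords=config.mito_keywords, qc_policy=config.qc_policy,
        length_policy=config.length_policy,
        identity_params=screen.IdentityParams(threshold=config.threshold),
        removals=removals, run_screen=config.run_screen)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = {"UNIQUE": result.unique, "LONGEST": result.longest}
    if config.variant != "both":
        variants = {config.variant: variants[config.variant]}
    for name, variant in variants.items():
        for gene, gene_entries in datasets.group_by_gene(variant).items():
            fasta = write_fasta((e.seqid, e.sequence) for e in gene_entries)
            (outdir / f"{name}_{gene.value}.fasta").write_text(fasta)
        fasta, tax = writers.write_rdp(variant, result.tree)
        (outdir / f"{name}.rdp.fasta").write_text(fasta)
        (outdir / f"{name}.rdp.taxonomy.txt").write_text(tax)
        (outdir / f"{name}.spingo.fasta").write_text(writers.write_spingo(variant))
    (outdir / "events.tsv").write_text(events_to_tsv(result.events))
    (outdir / "rename_map.tsv").write_text(rename_map_to_tsv(result.rename_map))
    if result.flag_report is not None:
        (outdir / "flags.tsv").write_text(
            result.flag_report.to_tsv(result.removed_per_gene))
    (outdir / "summary.tsv").write_text(result.summary_tsv())
    if config.described_counts_path is not None:
        counts = _read_described_counts(
            Path(config.described_counts_path).read_text())
        table = datasets.coverage_percentages(result.longest, counts)
        (outdir / "coverage.tsv").write_text(table.to_csv(sep="\t"))
    print(f"[mitoref] wrote {len(result.unique)} UNIQUE / "
          f"{len(result.longest)} LONGEST entries to {outdir}", file=sys.stderr)
    return result
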