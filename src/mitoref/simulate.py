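"""Seeded synthetic fixtures: annotated records with planted defects.

The generator fabricates everything the pipeline ingests — a
multi-record GenBank flatfile, a taxdump-dialect taxonomy, and a
machine-readable truth table — so every curation stage can be tested
end to end without downloading anything.

The emulated world is deliberately simple: each phylum holds two
classes of two orders each, one family per order, and monotypic genera.
Per-species gene sequences are independent random nucleotide strings
(so unrelated sequences sit far below any clustering threshold), and
haplotypes of one species differ by a handful of substitutions (≤1% by
default) so they fall into one cluster while remaining distinct
haplotypes.  Feature labels are drawn from the common GenBank label
variants for each gene, and one gene is annotated on the reverse
strand to exercise orientation handling.  No attempt is made to mimic
codon structure or phylogenetic realism.

Planted defect categories (disjoint sets of species/records):

==================  =====================================================
category            effect / expected audit reason
==================  =====================================================
NON_BINOMIAL        genus-only species name → NO_SPECIES_RANK
FORBIDDEN_TOKEN     'cf.' inside the species name → FORBIDDEN_TOKEN
BLACKLISTED         a known non-Latin identifier → BLACKLISTED_ID
TOO_SHORT/TOO_LONG  single-gene record outside the gene's length window
MISLABEL            exact copy of a donor, relabelled to a sister order
                    → MISLABEL_FLAGGED (the donor is flagged too)
DUPLICATE_NAME      same genus name planted in a second phylum; retained,
                    resolved by renaming
MISSING_RANK        family node absent from the taxdump; retained with a
                    placeholder rank
NON_MITO            nuclear record → NOT_MITO
NON_METAZOA         fungal record → NOT_METAZOA
==================  =====================================================
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .datasets import DEFAULT_LENGTH_WINDOWS
from .events import Reason
from .genes import CanonicalGene, reverse_complement
from .taxonomy import QCPolicy

#: Typical annotated lengths (nt) used for clean fixture sequences.
BASE_LENGTHS: dict[CanonicalGene, int] = {
    CanonicalGene.srRNA: 950, CanonicalGene.lrRNA: 1200,
    CanonicalGene.A6: 675, CanonicalGene.A8: 160,
    CanonicalGene.COI: 658, CanonicalGene.COII: 690,
    CanonicalGene.COIII: 785, CanonicalGene.Cytb: 1140,
    CanonicalGene.ND1: 960, CanonicalGene.ND2: 1040,
    CanonicalGene.ND3: 350, CanonicalGene.ND4: 1380,
    CanonicalGene.ND4L: 290, CanonicalGene.ND5: 1080,
    CanonicalGene.ND6: 520,
}

#: Label variants offered per gene: (gene qualifier choices, product choices).
_LABEL_VARIANTS: dict[CanonicalGene, tuple[list[str], list[str]]] = {
    CanonicalGene.srRNA: (["srRNA", "12S rRNA", "rrnS"],
                          ["12S ribosomal RNA", "small subunit ribosomal RNA"]),
    CanonicalGene.lrRNA: (["lrRNA", "16S rRNA", "rrnL"],
                          ["16S ribosomal RNA", "large subunit ribosomal RNA"]),
    CanonicalGene.A6: (["ATP6", "atp6"], ["ATP synthase F0 subunit 6"]),
    CanonicalGene.A8: (["ATP8", "atp8"], ["ATP synthase F0 subunit 8"]),
    CanonicalGene.COI: (["COI", "COX1", "CO1"],
                        ["cytochrome c oxidase subunit I",
                         "cytochrome oxidase subunit 1"]),
    CanonicalGene.COII: (["COII", "COX2"], ["cytochrome c oxidase subunit II"]),
    CanonicalGene.COIII: (["COIII", "COX3"], ["cytochrome c oxidase subunit III"]),
    CanonicalGene.Cytb: (["cytb", "cob", "CYTB"],
                         ["cytochrome b", "cytochrome b apoenzyme"]),
    CanonicalGene.ND1: (["ND1", "nad1"], ["NADH dehydrogenase subunit 1"]),
    CanonicalGene.ND2: (["ND2", "nad2"], ["NADH dehydrogenase subunit 2"]),
    CanonicalGene.ND3: (["ND3", "nad3"], ["NADH dehydrogenase subunit 3"]),
    CanonicalGene.ND4: (["ND4", "nad4"], ["NADH dehydrogenase subunit 4"]),
    CanonicalGene.ND4L: (["ND4L", "nad4L"], ["NADH dehydrogenase subunit 4L"]),
    CanonicalGene.ND5: (["ND5", "nad5"], ["NADH dehydrogenase subunit 5"]),
    CanonicalGene.ND6: (["ND6", "nad6"], ["NADH dehydrogenase subunit 6"]),
}

#: Gene annotated on the reverse strand (as ND6 is in real mitogenomes).
_REVERSE_GENES = frozenset({CanonicalGene.ND6, CanonicalGene.Cytb})

_SYLLABLES = ("ba", "be", "bi", "bo", "bu", "da", "de", "di", "do", "du",
              "ga", "ge", "gi", "go", "gu", "la", "le", "li", "lo", "lu",
              "ma", "me", "mi", "mo", "mu", "na", "ne", "ni", "no", "nu",
              "ra", "re", "ri", "ro", "ru", "ta", "te", "ti", "to", "tu",
              "va", "ve", "vi", "vo", "za", "zi")


@dataclass(frozen=True)
class PlantedCounts:
    """How many records/species to corrupt, per defect category."""

    non_binomial: int = 0
    forbidden_token: int = 0
    blacklisted: int = 0
    too_short: int = 0
    too_long: int = 0
    duplicate_name_conflicts: int = 0
    cross_order_mislabels: int = 0
    missing_rank: int = 0
    non_mito: int = 0
    non_metazoa: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    seed: int
    n_phyla: int = 3
    n_species_per_phylum: int = 8
    genes_per_species: tuple[CanonicalGene, ...] = (
        CanonicalGene.COI, CanonicalGene.srRNA, CanonicalGene.Cytb)
    haplotypes_per_species: int = 2
    mutation_rate: float = 0.005
    planted: PlantedCounts = field(default_factory=PlantedCounts)

    def __post_init__(self) -> None:
        if self.n_phyla < 1 or self.n_species_per_phylum < 1:
            raise ValueError("need at least one phylum and one species")
        if not self.genes_per_species:
            raise ValueError("genes_per_species must be non-empty")
        if not (0.0 <= self.mutation_rate <= 0.01):
            raise ValueError("within-species mutation rate must be ≤ 1%")


@dataclass(frozen=True)
class TruthRow:
    accession: str
    category: str
    expected_reason: Reason | None


@dataclass
class TruthTable:
    """Per-record planted category and expected audit reason."""

    rows: dict[str, TruthRow] = field(default_factory=dict)

    def add(self, accession: str, category: str,
            reason: Reason | None) -> None:
        if accession in self.rows:
            raise ValueError(f"duplicate truth entry {accession}")
        self.rows[accession] = TruthRow(accession, category, reason)

    def expected_pairs(self) -> set[tuple[str, str]]:
        """The (accession, reason) pairs the audit trail must contain."""
        return {
            (r.accession, r.expected_reason.value)
            for r in self.rows.values() if r.expected_reason is not None
        }

    def accessions(self, *categories: str) -> list[str]:
        return sorted(a for a, r in self.rows.items() if r.category in categories)

    def to_tsv(self) -> str:
        lines = ["accession\tcategory\texpected_reason"]
        for acc in sorted(self.rows):
            row = self.rows[acc]
            reason = row.expected_reason.value if row.expected_reason else ""
            lines.append(f"{acc}\t{row.category}\t{reason}")
        return "\n".join(lines) + "\n"


@dataclass
class FixtureBundle:
    """Everything :func:`generate` emits."""

    flatfile: str
    nodes_dmp: str
    names_dmp: str
    truth: TruthTable


@dataclass
class _Species:
    name: str            # binomial (or planted defect name)
    genus: str
    phylum_i: int
    class_i: int         # 0/1 within phylum
    order_i: int         # 0/1 within class
    category: str = "CLEAN"
    taxid: int = 0
    copy_of: "_Species | None" = None


class _NameFactory:
    def __init__(self, rng: random.Random, policy: QCPolicy):
        self.rng = rng
        self.used: set[str] = set()
        self.bad = tuple(t.casefold() for t in policy.forbidden_tokens)

    def word(self, n_syllables: int = 3, capital: bool = True) -> str:
        while True:
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables))
            if capital:
                w = w.capitalize()
            low = w.casefold()
            if w in self.used or any(t in low for t in self.bad):
                continue
            self.used.add(w)
            return w


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def _mutate(rng: random.Random, seq: str, n_subs: int) -> str:
    """Apply exactly *n_subs* substitutions at distinct positions."""
    positions = rng.sample(range(len(seq)), n_subs)
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def _assign_categories(spec: FixtureSpec,
                       species: list[_Species]) -> None:
    p = spec.planted
    wanted = (
        [("NON_BINOMIAL", p.non_binomial), ("FORBIDDEN_TOKEN", p.forbidden_token),
         ("BLACKLISTED", p.blacklisted), ("TOO_SHORT", p.too_short),
         ("TOO_LONG", p.too_long), ("MISSING_RANK", p.missing_rank),
         ("MISLABEL", p.cross_order_mislabels)]
    )
    total = sum(n for _, n in wanted)
    if p.cross_order_mislabels:
        # each mislabel needs a clean same-class donor in the sister order
        total += p.cross_order_mislabels
    if total > len(species):
        raise ValueError(
            f"fixture too small: {total} planted species requested, "
            f"{len(species)} available")
    # spread plants across phyla by striding through the species list
    order = sorted(range(len(species)),
                   key=lambda i: (i % spec.n_phyla, i // spec.n_phyla))
    cursor = 0
    for category, count in wanted:
        for _ in range(count):
            species[order[cursor]].category = category
            cursor += 1
    # pair each mislabel with a clean donor: same phylum & class, other order
    for sp in [s for s in species if s.category == "MISLABEL"]:
        donor = next(
            (d for d in species
             if d.category == "CLEAN" and d.phylum_i == sp.phylum_i
             and d.class_i == sp.class_i and d.order_i != sp.order_i),
            None)
        if donor is None:
            raise ValueError(
                "infeasible fixture: no clean same-class/other-order donor "
                "available for a planted mislabel")
        donor.category = "MISLABEL_DONOR"
        sp.copy_of = donor


def _species_reason(category: str) -> Reason | None:
    return {
        "NON_BINOMIAL": Reason.NO_SPECIES_RANK,
        "FORBIDDEN_TOKEN": Reason.FORBIDDEN_TOKEN,
        "BLACKLISTED": Reason.BLACKLISTED_ID,
        "TOO_SHORT": Reason.LENGTH_OUT_OF_RANGE,
        "TOO_LONG": Reason.LENGTH_OUT_OF_RANGE,
        "MISLABEL": Reason.MISLABEL_FLAGGED,
        "MISLABEL_DONOR": Reason.MISLABEL_FLAGGED,
        "NON_MITO": Reason.NOT_MITO,
        "NON_METAZOA": Reason.NOT_METAZOA,
    }.get(category)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build one deterministic fixture bundle from *spec*.

    Same seed, same spec → byte-identical outputs.  Clean records pass
    every filter; each planted defect triggers exactly its expected
    audit reason (see module docstring).
    """
    rng = random.Random(spec.seed)
    policy = QCPolicy()
    names = _NameFactory(rng, policy)

    # ---- taxonomy scaffold -----------------------------------------
    blacklist_cycle = list(policy.blacklist_ids)
    phyla = [names.word() for _ in range(spec.n_phyla)]
    classes = {(pi, ci): names.word()
               for pi in range(spec.n_phyla) for ci in range(2)}
    orders = {(pi, ci, oi): names.word()
              for pi in range(spec.n_phyla) for ci in range(2)
              for oi in range(2)}
    families = {key: names.word() for key in orders}

    species: list[_Species] = []
    for pi in range(spec.n_phyla):
        for si in range(spec.n_species_per_phylum):
            slot = si % 4
            ci, oi = slot // 2, slot % 2
            genus = names.word()
            epithet = names.word(capital=False)
            species.append(_Species(
                name=f"{genus} {epithet}", genus=genus,
                phylum_i=pi, class_i=ci, order_i=oi))
    _assign_categories(spec, species)

    # rewrite names for taxonomy defect plants
    n_black = 0
    for sp in species:
        if sp.category == "NON_BINOMIAL":
            sp.name = sp.genus
        elif sp.category == "FORBIDDEN_TOKEN":
            sp.name = f"{sp.genus} cf. {sp.name.split()[1]}"
        elif sp.category == "BLACKLISTED":
            sp.name = f"{sp.genus} {blacklist_cycle[n_black % len(blacklist_cycle)]}"
            n_black += 1

    # duplicate-name plants: reuse a clean genus name in another phylum
    dup_done = 0
    if spec.planted.duplicate_name_conflicts:
        clean = [s for s in species if s.category == "CLEAN"]
        for a in clean:
            if dup_done >= spec.planted.duplicate_name_conflicts:
                break
            b = next((s for s in clean
                      if s.phylum_i != a.phylum_i and s is not a
                      and s.category == "CLEAN"), None)
            if b is None:
                raise ValueError(
                    "infeasible fixture: duplicate-name plants need clean "
                    "species in at least two phyla")
            b.genus = a.genus
            b.name = f"{a.genus} {b.name.split()[1]}"
            b.category = "DUPLICATE_NAME"
            a.category = "DUPLICATE_NAME_KEPT"
            dup_done += 1

    # ---- taxdump tables --------------------------------------------
    nodes: list[tuple[int, int, str]] = []  # taxid, parent, rank
    node_names: dict[int, str] = {}
    next_id = 1

    def add_node(name: str, parent: int, rank: str) -> int:
        nonlocal next_id
        taxid = next_id
        next_id += 1
        nodes.append((taxid, parent if parent else taxid, rank))
        node_names[taxid] = name
        return taxid

    root_id = add_node("root", 0, "no rank")
    euk_id = add_node("Eukaryota", root_id, "superkingdom")
    metazoa_id = add_node("Metazoa", euk_id, "kingdom")
    phylum_ids = [add_node(p, metazoa_id, "phylum") for p in phyla]
    class_ids = {k: add_node(v, phylum_ids[k[0]], "class")
                 for k, v in sorted(classes.items())}
    order_ids = {k: add_node(v, class_ids[k[:2]], "order")
                 for k, v in sorted(orders.items())}
    family_ids = {k: add_node(v, order_ids[k], "family")
                  for k, v in sorted(families.items())}
    for sp in species:
        fam_key = (sp.phylum_i, sp.class_i, sp.order_i)
        if sp.category == "MISSING_RANK":
            genus_parent = order_ids[fam_key]  # family node omitted
        else:
            genus_parent = family_ids[fam_key]
        genus_id = add_node(sp.genus, genus_parent, "genus")
        sp.taxid = add_node(sp.name, genus_id, "species")

    # a fungal path for NON_METAZOA plants
    fungal_taxid = None
    if spec.planted.non_metazoa:
        fungi = add_node("Fungi", euk_id, "kingdom")
        f_phy = add_node("Ascomycota", fungi, "phylum")
        f_cla = add_node("Saccharomycetes", f_phy, "class")
        f_ord = add_node("Saccharomycetales", f_cla, "order")
        f_fam = add_node("Saccharomycetaceae", f_ord, "family")
        f_gen = add_node("Saccharomyces", f_fam, "genus")
        fungal_taxid = add_node("Saccharomyces cerevisiae", f_gen, "species")

    nodes_dmp = "".join(
        f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r in nodes)
    names_dmp = "".join(
        f"{t}\t|\t{node_names[t]}\t|\t\t|\tscientific name\t|\n"
        for t, _, _ in nodes)

    # ---- sequences and records -------------------------------------
    truth = TruthTable()
    bio_records: list[SeqRecord] = []
    acc_counter = 0

    def next_accession() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:06d}"

    # per-species haplotype sequences, genes in canonical order
    gene_order = [g for g in CanonicalGene if g in set(spec.genes_per_species)]
    haplotypes: dict[int, list[dict[CanonicalGene, str]]] = {}
    for idx, sp in enumerate(species):
        if sp.copy_of is not None:
            continue  # filled after donors
        if sp.category in ("TOO_SHORT", "TOO_LONG"):
            gene = gene_order[0]
            lo, hi = DEFAULT_LENGTH_WINDOWS[gene]
            n = lo - 1 if sp.category == "TOO_SHORT" else hi + 1
            haplotypes[idx] = [{gene: _random_seq(rng, n)}]
            continue
        base = {g: _random_seq(rng, BASE_LENGTHS[g]) for g in gene_order}
        haps = [dict(base)]
        for _ in range(1, spec.haplotypes_per_species):
            hap = {}
            for g in gene_order:
                n_subs = max(1, round(spec.mutation_rate * len(base[g])))
                hap[g] = _mutate(rng, base[g], n_subs)
            haps.append(hap)
        haplotypes[idx] = haps
    for idx, sp in enumerate(species):
        if sp.copy_of is not None:  # exact relabelled copies of the donor
            haplotypes[idx] = [dict(h)
                               for h in haplotypes[species.index(sp.copy_of)]]

    for idx, sp in enumerate(species):
        reason = _species_reason(sp.category)
        for hap in haplotypes[idx]:
            acc = next_accession()
            truth.add(acc, sp.category, reason)
            bio_records.append(
                _build_record(rng, acc, sp, hap, gene_order,
                              phyla, classes, orders, families))

    for _ in range(spec.planted.non_mito):
        acc = next_accession()
        truth.add(acc, "NON_MITO", Reason.NOT_MITO)
        bio_records.append(_build_foreign_record(
            rng, acc, organism="Homo sapiens",
            definition="Homo sapiens BRCA1 mRNA, complete cds",
            taxid=None, lineage=["Eukaryota", "Metazoa", "Chordata"],
            mito=False))
    for _ in range(spec.planted.non_metazoa):
        acc = next_accession()
        truth.add(acc, "NON_METAZOA", Reason.NOT_METAZOA)
        bio_records.append(_build_foreign_record(
            rng, acc, organism="Saccharomyces cerevisiae",
            definition="Saccharomyces cerevisiae mitochondrion, partial genome",
            taxid=fungal_taxid, lineage=["Eukaryota", "Fungi", "Ascomycota"],
            mito=True))

    handle = io.StringIO()
    SeqIO.write(bio_records, handle, "genbank")
    return FixtureBundle(flatfile=handle.getvalue(), nodes_dmp=nodes_dmp,
                         names_dmp=names_dmp, truth=truth)


def _build_record(rng, acc, sp, hap, gene_order,
                  phyla, classes, orders, families) -> SeqRecord:
    spacer = _random_seq(rng, 20)
    parts: list[str] = [spacer]
    features: list[SeqFeature] = []
    pos = len(spacer)
    for gene in gene_order:
        if gene not in hap:
            continue
        sense = hap[gene]
        reverse = gene in _REVERSE_GENES
        segment = reverse_complement(sense) if reverse else sense
        start, end = pos, pos + len(segment)
        location = SimpleLocation(start, end, strand=-1 if reverse else 1)
        gene_labels, product_labels = _LABEL_VARIANTS[gene]
        style = rng.randrange(3)  # gene only / product only / both
        qualifiers = {}
        if style in (0, 2):
            qualifiers["gene"] = [rng.choice(gene_labels)]
        if style in (1, 2):
            qualifiers["product"] = [rng.choice(product_labels)]
        kind = "rRNA" if gene in (CanonicalGene.srRNA, CanonicalGene.lrRNA) else "CDS"
        features.append(SeqFeature(location, type=kind, qualifiers=qualifiers))
        parts.append(segment)
        parts.append(_random_seq(rng, 20))
        pos = end + 20
    sequence = "".join(parts)
    lineage = ["Eukaryota", "Metazoa", phyla[sp.phylum_i],
               classes[(sp.phylum_i, sp.class_i)],
               orders[(sp.phylum_i, sp.class_i, sp.order_i)],
               families[(sp.phylum_i, sp.class_i, sp.order_i)], sp.genus]
    with_organelle = rng.random() < 0.7
    definition = (f"{sp.name} mitochondrion, partial genome"
                  if with_organelle or rng.random() < 0.5
                  else f"{sp.name} mitochondrial DNA, partial sequence")
    source_quals: dict[str, list[str]] = {
        "organism": [sp.name],
        "mol_type": ["genomic DNA"],
        "db_xref": [f"taxon:{sp.taxid}"],
    }
    if with_organelle:
        source_quals["organelle"] = ["mitochondrion"]
    source = SeqFeature(SimpleLocation(0, len(sequence), strand=1),
                        type="source", qualifiers=source_quals)
    rec = SeqRecord(
        Seq(sequence), id=f"{acc}.1", name=acc, description=definition)
    rec.annotations.update({
        "molecule_type": "DNA", "topology": "linear",
        "data_file_division": "INV", "date": "01-JAN-2016",
        "accessions": [acc], "organism": sp.name, "taxonomy": lineage,
    })
    rec.features = [source] + features
    return rec


def _build_foreign_record(rng, acc, organism, definition, taxid,
                          lineage, mito) -> SeqRecord:
    sequence = _random_seq(rng, 400)
    quals: dict[str, list[str]] = {
        "organism": [organism], "mol_type": ["genomic DNA"]}
    if taxid is not None:
        quals["db_xref"] = [f"taxon:{taxid}"]
    if mito:
        quals["organelle"] = ["mitochondrion"]
    source = SeqFeature(SimpleLocation(0, len(sequence), strand=1),
                        type="source", qualifiers=quals)
    cds = SeqFeature(SimpleLocation(50, 350, strand=1), type="CDS",
                     qualifiers={"gene": ["BRCA1" if not mito else "COI"]})
    rec = SeqRecord(Seq(sequence), id=f"{acc}.1", name=acc,
                    description=definition)
    rec.annotations.update({
        "molecule_type": "DNA", "topology": "linear",
        "data_file_division": "PLN", "date": "01-JAN-2016",
        "accessions": [acc], "organism": organism, "taxonomy": list(lineage),
    })
    rec.features = [source, cds]
    return rec
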