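# mitoref

Quality-filtered, taxonomically curated reference datasets of metazoan
mitochondrial gene sequences, built for automated taxonomic assignment
of environmental (metabarcoding / metagenetic) sequence data.

Community surveys of animals increasingly target mitochondrial markers
— above all *COI*, the standard animal barcode — because they resolve
taxa far better than nuclear rRNA genes. Assignment tools such as the
RDP Classifier, SPINGO, and BLAST+ are only as good as their reference
database, and raw GenBank annotations are noisy: heterogeneous gene
labels, missing or non-binomial species names, wildly out-of-range
sequence lengths, and outright mislabelled sequences. `mitoref`
implements a complete curation pipeline from annotated GenBank-style
flatfiles to classifier-ready per-gene reference datasets:

1. **Pre-filtering** — keep mitochondria-related (organelle qualifier
   or definition keyword) and metazoan records.
2. **Gene binning** — normalise the heterogeneous CDS/rRNA labels to
   the 15 mitochondrial genes (*srRNA, lrRNA, A6, A8, COI–COIII, Cytb,
   ND1–ND6, ND4L*) through an extensible synonym table, excise the
   annotated region (strand-aware), and partition into per-gene bins.
3. **Taxonomy curation** — resolve eight-rank lineages
   (Root…Species) from an NCBI-taxdump-dialect taxonomy; remove
   lineages without a binomial species name, with uncertainty tokens
   ('cf.', 'aff.', 'sp.', …), or with known non-Latin identifiers;
   rename duplicated higher-taxon names (*Automolus* → *Automolus01*).
4. **Length windows** — drop per-gene length outliers (e.g. *COI*
   retained in 100–2,000 nt), which are enriched in mis-annotations.
5. **Dereplication** — build the **UNIQUE** variant (every distinct
   haplotype per species) and the **LONGEST** variant (single longest
   sequence per species).
6. **Mislabel screen** — greedy centroid clustering of each gene's
   UNIQUE bin at 99% semi-global identity; clusters mixing two or more
   phyla, classes, or orders are flagged, and an expert-supplied
   adjudication list drives removals.
7. **Export** — RDP Classifier training set (``id*name*parent*depth*rank``
   taxonomy + lineage-annotated FASTA), SPINGO reference FASTA, and a
   BLAST-ready FASTA, all byte-deterministic.

A seeded synthetic-fixture generator (`mitoref.simulate`) fabricates
flatfiles, taxonomies, and a truth table with planted defects of every
category, so the whole pipeline is testable offline.

## Worked example

```python
from mitoref import curate, generate, FixtureSpec, PlantedCounts

spec = FixtureSpec(seed=42, n_phyla=3, n_species_per_phylum=10,
                   planted=PlantedCounts(forbidden_token=2,
                                         cross_order_mislabels=1))
bundle = generate(spec)
result = curate(bundle.flatfile, bundle.nodes_dmp, bundle.names_dmp)
print(result.stage_counts)
```

prints

```
{'parsed': 60, 'mitochondrial': 60, 'metazoan': 60,
 'gene_assigned_entries': 180, 'lineage_qc_passed': 56,
 'length_passed_entries': 168, 'unique_entries': 168,
 'longest_entries': 84}
```

60 records were parsed (30 species × 2 haplotypes, 3 genes each =
180 gene entries). The two species planted with a 'cf.' uncertainty
token lose their 4 records at taxonomy QC (56 of 60 pass), leaving
168 entries. All haplotypes are distinct, so UNIQUE keeps all 168;
LONGEST keeps one sequence per surviving species and gene
(28 species × 3 genes = 84). The audit trail names each removal:

```
>>> result.events[0]
CurationEvent(subject='SYN000001', stage='taxonomy_qc',
              reason=FORBIDDEN_TOKEN,
              detail="species='Vomabo cf. gubima' contains 'cf.'")
```

and the planted cross-order mislabel shows up in the screen report:

```
>>> result.flag_report.counts[CanonicalGene.COI]
{'phylum': 0, 'class': 0, 'order': 1}
```

The same pipeline is available from the shell:

```
mitoref simulate --seed 42 --outdir fixture --forbidden 2 --mislabels 1
mitoref run --in fixture/records.gb --taxdump fixture --outdir out
```

which writes per-gene FASTAs (`UNIQUE_COI.fasta`, …), the RDP, SPINGO
and BLAST references, and the `events.tsv`/`flags.tsv`/`summary.tsv`
reports into `out/`.

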