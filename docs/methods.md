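# Methods

## The curation model

`mitoref` treats reference-database construction as a deterministic
filter-and-transform pipeline over annotated nucleotide records. Every
removal or flag is recorded as a `CurationEvent` with a reason code
from a closed vocabulary, so the set of retained entries plus the set
of event subjects always accounts for the full input — the audit trail
is a first-class output, not a log.

### Pre-filters

A record is *mitochondria-related* iff its source feature carries
`organelle="mitochondrion…"` or its definition line matches a keyword
(default `mitochondri`, `mitogenome`, case-insensitive). The keyword
route exists because nuclear-encoded mitochondrial genes carry no
organelle qualifier; the list is configurable since no canonical list
exists. *Metazoan* membership is an exact, case-sensitive match of the
node name `Metazoa` in the record's resolved ancestry (taxonomy names
are a controlled vocabulary; fuzzy matching would only add risk).

### Coordinates and excision

The flatfile dialect is 1-based inclusive; internally all spans are
0-based half-open, converted exactly once at parse time so no
off-by-one can accumulate. Compound locations are stored in ascending
genomic order; excision concatenates span slices and
reverse-complements the whole concatenation for minus-strand features,
so every binned sequence reads in the gene's sense orientation.
Features marked 5'/3'-partial are retained — length filtering, not
annotation completeness, decides later.

### Gene label normalisation

Labels are case-folded, stripped of `.,;:()`, and whitespace-collapsed
before lookup in a (feature kind, label) → gene synonym table. If the
`gene` and `product` qualifiers both resolve they must agree
(`AMBIGUOUS` otherwise); one resolving label suffices; neither means
`UNKNOWN`. Ambiguous and unknown features are discarded with events —
a reference sequence of uncertain gene identity is worse than a
missing one. The shipped default table covers the common GenBank label
variants; a user table (3-column TSV) extends or overrides it, and
`census_feature_labels` produces the frequency table a curator reviews
when extending it.

### Eight-rank lineages and QC

Classifiers of the RDP family train on a fixed-depth taxonomy, so each
lineage is exactly Root, Kingdom, Phylum, Class, Order, Family, Genus,
Species. Ranks missing from the source path are filled with a
placeholder `{nearest named neighbour}_{abbrev}` (e.g. `Automolus_fam`),
preferring the nearest real name below the gap; records with missing
intermediate ranks are retained rather than dropped, because real
deposited datasets contain such records and the species-level
information is still valuable. Placeholders are excluded from
duplicate-name resolution and from mislabel-mixing decisions.

Three QC filters run in order and report the first failure:

1. `NO_SPECIES_RANK` — species placeholder or fewer than two
   whitespace tokens (binomial presence proxies expert identification);
2. `FORBIDDEN_TOKEN` — any of the 11 uncertainty tokens
   (`cf.`, `aff.`, `sp.`, `environment`, `undescribed`, `uncultured`,
   `complex`, `unclassified`, `nom.`, `nud.`, `unidentif`) as a
   case-insensitive substring of any of the eight rank names. The
   substring scan can in principle false-positive on a legitimate name
   containing a token; this is accepted and visible in the audit trail;
3. `BLACKLISTED_ID` — the species name contains one of the known
   non-Latin identifiers `sp0936BC`, `MG98.09`, `sp0942A`, `EEG-2007`.

### Duplicate-name resolution

The same name at one rank under different parents (or at two ranks)
aborts classifier training. Occurrences of a conflicting name are
ordered by (rank depth, parent path); the first keeps the name, later
ones get two-digit suffixes `01`, `02`, … (three digits past 99; a
candidate colliding with an existing name skips to the next number).
A renamed genus is propagated into the first token of its species
binomials so the binomial stays consistent. The operation is
idempotent, and the rank-tree builder refuses residual duplicates.

### Length windows

Per-gene retained windows (nt, inclusive): srRNA 200–2000,
lrRNA 100–2500, A6 100–1000, A8 100–500, COI 100–2000, COII 100–1500,
COIII 100–1300, Cytb 100–1500, ND1 50–1200, ND2 150–1500, ND3 100–600,
ND4 150–2000, ND4L 100–700, ND5 150–2000, ND6 150–1500. Length
extremes are enriched in mis-annotations and demonstrably derail
naive-Bayes assignment, hence a hard window rather than a soft score.

### Dereplication

Haplotype identity is exact string equality after case-folding;
ambiguity codes are *not* expanded (an N-variant is a distinct
haplotype) — expansion would make dereplication non-deterministic in
spirit and collapse genuinely different records. UNIQUE keeps the
smallest-seqid carrier of each (gene, species, sequence); LONGEST
keeps the single longest sequence per (gene, species), ties to the
smallest seqid. Both outputs are sorted by (gene, species, seqid), so
results are independent of input order. Species identity is the
resolved (possibly conflict-renamed) species *name*, because the
output formats are name-keyed.

### Mislabel screen

Within the typical span of intra-specific variation (≥99% identity),
one cluster should hold one taxon at phylum, class, and order level.
Each gene's UNIQUE bin is clustered greedily: entries in decreasing
length order (ties by seqid), each joining the first centroid — in
creation order — reaching the identity threshold, else founding a new
cluster. Identity is defined as `1 − d / len(shorter)` where `d` is
the semi-global edit distance of the shorter sequence against the
best-matching substring of the longer (terminal gaps in the longer
sequence free; IUPAC ambiguity letters match only if literally equal).
This is symmetric, deterministic (no alignment-traceback tie-breaks),
and equals the matching-column fraction for the substitution-dominated
near-identical pairs the screen cares about. Strand handling is
forward-only: excision already orientation-normalised every entry.

An inverted 8-mer index prescreens centroid candidates: if identity
≥ t, at most `⌊(1−t)·m⌋` edits exist and each disturbs at most k of
the query's overlapping k-words, so at least `(m−k+1) − k·⌊(1−t)·m⌋`
query words must appear in the centroid. The bound only ever *skips*
pairs provably below threshold, so prescreened clustering is exactly
equal to exhaustive clustering (verified against an independent
full-matrix oracle in the test suite).

Clusters with ≥2 distinct non-placeholder labels at a level are
flagged; levels are counted independently. Deciding *which* member is
mislabelled needs phylogenetic judgement, so removal consumes an
adjudication list (one seqid per line); ids that were never flagged
are rejected, and unadjudicated flagged members are retained. No
screening is attempted below order level, where discordance can be
biological (introgression, synonymy) rather than erroneous.

### Output formats

RDP: `id*name*parentid*depth*rank` taxonomy lines (root id 0, parent
−1, rank `rootrank`; species depth always 7; nodes in depth-first
lexical order) plus a FASTA whose headers are
`{seqid}<TAB>Root;Kingdom;…;Species`, wrapped at 60 columns. SPINGO:
unwrapped FASTA, header `{seqid}` followed by six tab-separated ranks
phylum→species (species last, as species-mode classification
requires; the layout is a package choice since no normative column
order exists). BLAST input is the RDP FASTA verbatim — the
lineage-bearing headers keep hits interpretable. All writers are
byte-deterministic; `read_rdp` inverts `write_rdp` on its image and is
the round-trip contract (byte-parity with any externally hosted file
is a non-goal).

## The synthetic-fixture generator

The generator emulates what the pipeline must be robust to, not real
biology: each phylum holds two classes × two orders, one family per
order, monotypic genera; per-species gene sequences are independent
uniform-random nucleotide strings (unrelated pairs sit near 55–60%
identity, far below any threshold), and within-species haplotypes
differ by substitutions at ≤1% (default 0.5%) so they co-cluster at
99% while remaining distinct haplotypes. Feature labels are sampled
from the common GenBank variants; Cytb and ND6 are annotated on the
reverse strand. Default shape: 3 phyla × 8 species × 2 haplotypes ×
3 genes (COI, srRNA, Cytb).

Planted defects occupy disjoint species sets: non-binomial,
forbidden-token, and blacklisted species names; single-gene records
one nucleotide outside the length window; exact sequence copies
relabelled into a sister order (the donor is also expected to be
flagged — the screen cannot, and should not, tell copy from donor);
a genus name duplicated into a second phylum (retained, renamed);
a family node omitted from the taxdump (retained with placeholder);
plus non-mitochondrial and non-metazoan records. The truth table maps
every accession to its category and expected reason code.

What passing these tests does **not** show: robustness to real
GenBank's long-tailed label vocabulary beyond the shipped synonyms, to
chimeric or low-complexity sequences (random strings contain neither),
or to taxonomies with rank synonyms and merged nodes. The generator's
identity structure is also binary (≈100% within species/copies, ≈55%
between), so threshold behaviour *between* those regimes is exercised
only by the dedicated clustering-oracle tests.

## Numerical and degenerate-input choices

- Length bounds inclusive on both ends ("outside the range" read as a
  closed interval).
- Identity threshold default 0.99; threshold → 0 degenerates to one
  cluster, threshold 1.0 to exact-near-duplicate grouping.
- Equal-length identity takes the minimum distance over both alignment
  directions to guarantee symmetry.
- Empty inputs are valid everywhere: 15 empty bins, a root-only rank
  tree, empty variants, a zero-flag report.
- Malformed flatfile records (missing LOCUS/ORIGIN, truncated final
  record, non-IUPAC letters, duplicate accessions) produce per-record
  events and parsing continues.
- All orderings (bins, variants, tree nodes, report rows) are
  canonical sorts, so identical inputs give byte-identical outputs.

## Test problem sizes

The QC-recovery suite runs 20 seeded fixtures of 500 records each
(5 phyla × 50 species); clustering oracle equivalence runs 100 random
instances, 90 at 5–25 sequences × 60–300 nt and 10 at 30–50 sequences
× 400–600 nt, across thresholds 0.90–0.99. These sizes exercise every
code path (prescreen hit and miss, multi-member clusters, ties) while
keeping the full suite under two minutes.

## Known limitations

- The synonym table ships with common variants only; real-world runs
  should extend it from the label census.
- No translation/ORF validation of protein-coding genes and no
  detection of unannotated genes by similarity.
- No species-level synonym reconciliation against external registries.
- The screen's adjudication is external by design; the package never
  decides which cluster member is wrong.
- Single-process, desk-scale contract; no parallel execution.
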