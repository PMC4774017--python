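# Methods

This note documents the models, rules and numerical choices behind
`varbench`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

Regions are 0-based half-open (BED convention); variant positions are
1-based (VCF convention).  The conversion happens at exactly one boundary
(`RegionSet.contains` / `edge_distance` take 1-based positions).
Chromosome names are compared as exact strings — no "chr" aliasing — so
mismatched inputs fail loudly rather than silently intersecting nothing.
Symbolic and breakend ALT alleles are rejected: structural variants are
outside the benchmark's scope.  Only CHROM/POS/REF/ALT/QUAL/FILTER and one
sample's GT/DP are interpreted from VCF.

## Interval algebra

`RegionSet` stores per-chromosome sorted, merged intervals and implements
intersection, subtraction and union with base-set semantics: abutting
intervals merge, and `|A| = |A∩B| + |A\B|` holds exactly (asserted by
property tests against a per-base membership oracle).  `edge_distance`
counts the variant's own base as distance 0 from a boundary base, making
"within 50 bp of the inside edge" the inclusive test
`edge_distance ≤ 49`; the bound is configurable (`edge_bp`).

## Variant normalization and haplotype-aware matching

Variants are canonicalized by trimming shared leading/trailing bases
(keeping one anchor base for indels) and left-aligning indels against the
reference until irreducible; a test checks 300 random indels against an
exhaustive enumeration of equivalent representations.  Multi-allelic
records are split into per-ALT records before matching, with allele
indices of *other* ALTs remapped to reference.

Classification proceeds in three steps: (1) exact matching on the
normalized (chrom, pos, ref, alt) key; (2) clustering of all in-region
variants closer than 50 bp; (3) for clusters with unmatched records on
both sides, exhaustive diploid phasing — every record's alleles assigned
to two haplotypes, 2^h assignments over h heterozygous sites, capped at
h = 12 (an error above the cap) — and comparison of the unordered pair of
reconstructed window sequences.  Half-calls (`./1`) are treated as
heterozygous with a reference side.  Overlapping alleles on one haplotype
make that phasing unreconstructable, not an error.

Truth variants in-region partition into TP and FNV, PASS query variants
into TP and QV; these identities are asserted on every synthetic run.
An allele-level match with a discordant genotype counts as TP for
sensitivity but is emitted as a questionable-genotype diagnostic; the
`genotype_strict` switch demotes such pairs to FNV + QV instead.
Filtered (non-PASS) query records are excluded from matching and resurface
only in FN-cause attribution, mirroring how a default-filtered pipeline
actually behaves.

## Stratified sensitivity

A simple transcript-based consequence classifier assigns each SNV one of
non-synonymous / synonymous / truncating / splicing / other: splicing is
an SNV within 2 bp of an exon–intron boundary on the intron side; coding
SNVs are translated strand-aware through the standard genetic code
(stop-gain → truncating; stop-loss and start-loss are kept in
non-synonymous — the minimal defensible reading of the four clinical
classes); frameshift indels in the CDS are truncating; in-frame indels and
everything else fall to "other".  When a gene symbol has several
transcripts the longest CDS is used, so the ambiguity is deterministic.
A 1,000-SNV test checks the classifier against translating the whole CDS
before and after each edit, on both strands.

Confidence intervals are Wilson score without continuity correction
(via `statsmodels.proportion_confint`, cross-checked against the closed
form `n/(n+z²)` for x = n).  Wilson reproduces the printed benchmark
bounds — (0.801, 0.966) for 43/47 and 0.646, 0.924 for 7/7 and 47/47 — to
three decimals, which is why it was chosen over Clopper–Pearson or normal
approximations.

FN causes are non-exclusive: `filtered` (a raw call with the same
normalized key carries filter labels), `low_coverage` (depth < 10 — the
benchmark's hard threshold), `high_gc` (reference GC > 0.75 in a 100-bp
centered window; the window is configurable and chosen at read-length
scale since only the threshold is externally fixed), `repeat_class:<c>`
per containing track, else `unexplained`.

## Region characterization

Exons are merged across transcripts of a symbol before coverage, so
"exonic bases" is a per-gene base count without double counting.  Gene-set
summaries are base-weighted (covered exonic bases / total exonic bases);
the gene-averaged mean is emitted alongside because the two differ
whenever coverage correlates with gene length.  Exon-position classes are
strand-aware (first = 5′) and assigned by the precedence
first > last > second > penultimate > middle, which partitions the exons
of genes with fewer than five exons deterministically (a 3-exon gene is
first/second/last).  Low-confidence bases are attributed to the *first*
reason track containing them, in the supplied precedence order, so
overlapping annotations never double-count a base; the remainder is
reported as "unattributed".

## Uniqueness and alignability

A position is unique at k when its k-mer occurs exactly once among
forward-strand start positions genome-wide (matching how the classic
browser tracks were built; a reverse-complement-aware mode is a flag away
from the same machinery but not a default).  Alignability at (k, m) means
no *other* location matches within Hamming distance m, gapless.  K-mers
containing N are never unique or alignable, and an N counts as a mismatch
against everything including another N: undefined sequence cannot certify
a match.  The mismatch scan is vectorized over all pairwise shifts —
O(L·W) for a shift window W — and `window=None` gives the exact quadratic
scan used in tests; windows spanning the inter-chromosome sentinel are
excluded outright so junction artifacts cannot create phantom matches.
Exact mode handles megabase references in memory via a k-mer count table;
the implementation targets correctness at test scale, not 3-Gb genomes.

## Systematic-error sites

Evidence at a benchmark homozygous-reference site is any call whose
genotype contains a non-reference allele (or any call at all, for
sites-only inputs) with quality above the permissive threshold (default
> 2).  A platform flags a site when its evidencing dataset count equals
all of its datasets or exceeds two; for 3-dataset platforms the rules
coincide, and a 1-dataset platform trivially satisfies "all" — implemented
as written.  The reported ALT is the majority over evidence calls, ties
broken lexicographically with all observed ALTs retained.  Database
intersection requires chrom, normalized position, REF and at least one
shared ALT; indels are left-aligned first so shifted homopolymer
representations collapse to one site.

## The synthetic generator

The generator builds, from one seeded RNG, every input the pipeline
consumes, plus bookkeeping tables from which `expected_metrics` recounts
the expected outputs *without touching pipeline code* — the test suite's
oracle.

What it emulates, and the defaults (all configurable through `SimConfig`):

* **Genome**: 2 chromosomes × 500 kb of uniform random sequence.
* **Low-confidence structure**: 12% of the genome excluded, partitioned
  into precedence-ordered reason segments at exactly 47 / 34 / 15 / 4 %
  (reported structural variants, short tandem repeats, segmental
  duplications, simple repeats).  STR segments get homopolymer/tandem
  sequence and segdup segments get copied sequence written into their
  interiors with a 20-bp margin, so the excluded bases really are
  difficult; high-confidence regions are the exact complement.
* **Genes**: 80 models, 2–8 exons of 120–280 bp, introns 200–800 bp,
  random strand, CDS rewritten to a valid reading frame (ATG … stop, no
  internal stops).  A quarter of genes deliberately straddle SV-reason
  segments so gene coverage fractions have planted signal.  Gene sets
  emulate a small mandatory-reporting panel (8 genes), a disease-gene
  catalogue (24), and all coding genes.
* **Truth variants** (~3,050): per-stratum counts
  300 non-synonymous / 300 synonymous / 50 truncating / 40 splicing /
  2,300 intergenic + 30 adjacent phased SNV pairs, planted by editing
  codons to force each consequence; 67% heterozygous; 5% of intergenic
  variants planted outside the regions to exercise the OUTSIDE class;
  ≥ 60 bp spacing keeps matching clusters trivial except for the planted
  pairs.  Constrained strata are planted first through a shuffled
  exhaustive codon scan, so dense configurations fail loudly only when
  genuinely infeasible.
* **Query errors**: per-stratum sensitivity 0.95 (0.90 splicing); misses
  are 60% filter-removed (weighted single labels, 20% double) and 40%
  low-coverage (depth 2–9 at the site, against a floored
  negative-binomial depth model with mean 30); a 2% genotype-error rate
  flips het/hom on called variants; half the called SNV pairs are
  re-emitted as MNVs; 40 false calls are planted, half filtered
  (strand-bias-weighted) and half unfiltered QVs, 40% of those near an
  inside edge.
* **Panels and databases**: 2 platforms (3 and 4 datasets), 25 systematic
  sites injected under the all-or->2 rule, 10 sub-threshold noise sites
  (2 datasets) and 3 low-quality sites (qual ≤ 2) that must *not* be
  detected; database lists contain 50% / 12% of the systematic sites with
  matching ALTs plus wrong-ALT decoys and background entries.

Identical seed and configuration give byte-identical bundle files
(asserted).  What the generator does **not** emulate: read-level data
(no FASTQ/BAM, no error physics), linkage/population structure, realistic
base composition, overlapping transcripts, or multi-sample genetics.
Passing tests therefore certify the *analysis machinery* — classification,
counting, interval arithmetic, rule boundaries — on inputs with known
truth, not pipeline performance on real sequencing data.

## Problem sizes

The test suite runs the full pipeline on a 220-kb single-chromosome
configuration (30 genes, ~650 truth variants) chosen so a 20-seed
parameter-recovery sweep completes in seconds; the acceptance script runs
the generator's default 1-Mb scale with the alignability scan banded at a
2,000-bp shift window (duplication copies are planted within 1,500 bp, so
the banded scan sees them).  Oracle-equivalence tests use ≤ 2-kb sequences
where the quadratic scans are exact.

## Known limitations

* The haplotype matcher is exhaustive and therefore exponential in
  heterozygous sites per cluster; the 12-site cap turns pathological
  clusters into explicit errors rather than silent slowdowns.
* The consequence classifier is transcript-minimal: one transcript per
  gene, no UTR/promoter classes, no splice-region subtleties beyond the
  2-bp rule.
* Sensitivity is the only accuracy metric with a CI; precision over QVs is
  reported as counts because the truth of a QV is, by definition,
  unresolved.
* Uniqueness tracks count forward-strand occurrences only by default.
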