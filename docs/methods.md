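# Methods

This note records the models, rules and defaults behind `matmine`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3 keeps its native
1-based inclusive convention at the file boundary, FASTA is wrapped at 60
columns on write. Gene models carry CDS segments sorted by genomic
coordinate (transcription order is the reverse for minus-strand genes)
and free-text functional labels taken from GFF3 `product`/`Note`
attributes. Locus discovery is label-driven by design: gene function
annotation is treated as an input, matched case-insensitively as
substrings against configurable keyword lists, rather than re-derived
with profile HMMs. Translation uses the standard codon table (id 1);
codons containing N translate to X; an internal stop flags the record
instead of failing, so annotation glitches surface as warnings.

Assembly statistics follow the usual conventions: N50 is the smallest
length L such that contigs ≥ L cover half the assembly; the GC
denominator excludes N (undetermined bases carry no composition
information).

## Telomere detection

Chromosome termini are scanned for **exact tandem arrays** of a monomer —
defaults (CCCCCTAA) at 5' and its reverse complement (TTAGGGGG) at 3'. A
terminus is telomeric when a maximal run of ≥ `min_copies` (default 3)
exact copies begins (5') or ends (3') within `max_offset` (default
1000 bp) of the terminus; when several runs qualify, the one nearest the
terminus wins, telomeres being terminal by definition. Exact matching
keeps the detector auditable (planting k copies is always detected with
copies = k) at the cost of ignoring degenerate monomer variants and
rotations; both are deliberate non-features, the latter left as a config
extension point. The minimum copy number and offset tolerance are
package decisions, not literature constants.

## A locus

"Head-to-head" is operationalised as divergent transcription: the
leftmost gene on the minus strand, the rightmost on plus, intervals
non-overlapping, intergenic gap ≤ `max_gap` (default 10 kb — generous for
fungal intergenic distances; overlapping divergent genes are rejected
because the depicted locus architecture shows separated genes).
Candidate genes are those labelled with any of `homeobox`, `homeodomain`,
`HD1`, `HD2`; all qualifying pairs are returned sorted by gap, and the
pipeline keeps the smallest-gap pair. The locus region is the anchor
union extended by `flank` (default 30 kb, putting the region at the
~70-kb scale reported for tremellaceous A loci); how those published
locus boundaries were chosen is unstated, so the flank is a free
parameter, not an assertion.

## B locus

Receptors are located by label (`pheromone receptor`, `STE3`). Both
10-kb genomic flanks of the receptor are enumerated for maximal
ATG-to-stop ORFs on both strands (minimum 75 nt including the stop, the
NCBI ORF finder's default; one ORF per stop codon, nested ATGs
suppressed unless requested). Each translated peptide is scored against
two rules:

- **CaaX**: the last four residues are C, a, a, X with a ∈ {A,V,L,I,G}
  and X ∈ {A,S,M,Q,C};
- **N-terminal signatures**: the dipeptides AF and ER each occur, in
  either order, within the first `sig_window` = 40 residues. The
  signatures are taken as literal dipeptides — a positional or
  alignment-derived consensus would need a curated precursor alignment
  that is out of scope; the window is configurable. Peptides outside the
  typical 20–120 aa precursor range are flagged, never dropped, to keep
  the evidence auditable.

The verdict is the conjunction, and every call records per-rule evidence.
The locus anchors are the receptor plus the nearest verdict-true
precursor (falling back to a `pheromone precursor`-labelled gene);
annotated genes strictly between the anchors form the insertion set that
distinguishes an "inserted" (matB2-like) architecture from the compact
adjacent one.

## Identity, alleles, compatibility

Percent identity comes from a global Needleman–Wunsch alignment under
BLOSUM62 with gap open 10 / extend 1, as matches over all alignment
columns (gap columns included; a switch excludes them). The method
behind published MAT-allele identity figures is generally unstated, so
both conventions are exposed and the defaults documented. Among
co-optimal alignments the aligner's first traceback is used; this is
deterministic for fixed inputs and scoring, which is all downstream
logic requires. Alleles are classed by **exact** protein identity
(identical marker proteins ⇒ same allele), labelled in first-seen strain
order; the pipeline concatenates HD1+HD2 (locus A) and PhB+STE3
(locus B) as the per-strain marker. Tetrapolar compatibility is simply
inequality at both loci; unknown alleles propagate as indeterminate, and
a bipolar (A-only) mode exists for reuse.

## Microsynteny and strain-specific genes

Locus genes are paired by reciprocal-best global identity with a 30%
match threshold — low enough that cross-allele receptors at ~35%
identity still pair. Matched pairs ordered along one locus are scanned
for maximal strictly-decreasing runs in the other locus's order
(length ≥ 2 ⇒ inverted block); unmatched genes form per-locus insertion
sets. Inversion calling is gene-order based, matching the gene-level
granularity of locus maps, not nucleotide alignment.

Genome-wide strain-specific genes use a zero-reciprocal-match rule with
an explicit hit definition instead of a search-engine e-value: a hit is
a local alignment (BLOSUM62, 10/1) with ≥ 30% identity covering ≥ 40% of
the gene. The identity denominator **includes gap columns**: measured on
synthetic proteomes, a gap-free denominator lets unrelated proteins
reach ~31–35% "identity" over 40% coverage through gappy chance
alignments, while true homologs — even at 35% positional divergence —
align nearly gaplessly and are unaffected. Exact sequence matches
short-circuit without alignment, and genes left unhit after the first
pass are re-checked as queries so the shortcut cannot hide a hit. An
e-value mode (Karlin–Altschul) is a possible extension, off by default.

## Synthetic genomes

The generator emulates the genome shape the pipeline targets: 12
chromosomes, each capped by five exact telomere monomer copies per end;
an HD1/HD2 divergent pair (HD1 with a spliced CDS) on chromosome 5 with
conserved neighbours; PhB + STE3 on chromosome 11 with conserved
flanking genes, either adjacent or separated by a three-gene insertion
block; background genes (30% two-exon) with neutral labels; i.i.d.
intergenic sequence at 53.65% GC (the observed assembly average for the
target clade — composition realism without repeat modelling). Default
inter-allele divergence targets are HD1 78.30 / HD2 77.22 / PhB 76.72 /
STE3 35.10 percent identity, exercising both the high- and low-identity
matching regimes. Divergent alleles are made by substituting random
positions until positional identity first reaches the target; the PhB
variant freezes its first six and last four residues so both alleles
keep the AF/ER and CaaX motifs, and the precursor is 60 aa so the
calibration has enough positions to hit its target. Two decoy ORFs are
planted in the receptor flanks, one failing only CaaX, one failing only
the N-terminal rule, as specificity controls; a TAA guard immediately
upstream of each planted single-exon ORF pins its reading frame so the
longest-per-stop scanner recovers exactly the planted peptide.

All strains share one background layout, so cross-strain differences are
exactly the planted ones; all randomness flows from one seed (per-gene
CDS seeds are derived stably from it, so strains sharing an allele share
bytes), and identical inputs are byte-identical outputs. The truth
manifest records chromosome lengths, telomere spans, locus coordinates
and gene ids, allele labels, insertion sets, decoys and expected
compatible pairs; a validator cross-checks every claim against the
emitted sequences.

**What passing does and does not show.** The benchmark plants exact
telomere arrays, clean single-copy loci, correct functional labels and
intron-poor genes; real assemblies have degenerate telomeric repeats,
annotation noise, paralogs and missing labels. Recovery on the benchmark
demonstrates the logic end to end (coordinates, filtering, typing,
compatibility, synteny), not robustness to annotation error — the
label-driven design inherits whatever the input annotation got wrong.

## Problem sizes and numerics

The default test scale uses 30–60 kb chromosomes (7–11 background genes
each), chosen so a full four-strain pipeline run, including all pairwise
synteny and strain-specific scans, completes in well under a minute; a
`paper` scale profile (megabase chromosomes) exists for soak testing.
Identity values are reported to two decimals; ties in reciprocal-best
pairing break lexicographically by gene id; degenerate inputs (empty
genomes, single strains, missing loci) degrade to warnings and skipped
cross-strain stages rather than failures, with a non-zero exit only when
every strain fails.

## Known limitations

- Exact-tandem telomere matching undercounts degenerate arrays.
- Label-driven locus discovery cannot find unannotated HD or receptor
  genes (no HMM fallback by design).
- The AF/ER rule is a literal-dipeptide operationalisation of a loosely
  stated motif; true precursor alignments may justify a positional model.
- Allele classing by exact identity treats a single amino-acid variant
  as a new allele; a similarity-threshold mode exists but is off by
  default.
- Strain-specific gene calling with identity+coverage is more
  conservative than a calibrated e-value at detecting remote homology.
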