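# matmine

Mating-type locus mining and compatibility genetics for haploid fungal
genome assemblies.

Tetrapolar basidiomycetes (jelly fungi such as *Naematelia* and
*Tremella*, and many mushrooms) control mating through two unlinked
mating-type (MAT) loci. The **A locus** encodes a pair of homeodomain
transcription factors (*HD1*, *HD2*) transcribed divergently
("head-to-head"); the **B locus** couples a pheromone receptor (*STE3*, a
seven-transmembrane GPCR) with short lipopeptide pheromone precursors.
Two monokaryons can mate only when they differ at **both** loci:

    compatible(g1, g2)  ⇔  A(g1) ≠ A(g2)  ∧  B(g1) ≠ B(g2)

`matmine` takes per-strain genome FASTA + GFF3 annotation and performs the
genome-characterisation steps around these loci:

- **Telomere detection** — exact tandem arrays of the telomere monomers
  (CCCCCTAA)n at 5' termini and (TTAGGGGG)n at 3' termini, with per-genome
  completeness totals (a 12-chromosome telomere-to-telomere assembly has
  24 arrays).
- **A-locus discovery** — label-driven homeodomain candidates, divergent
  (head-to-head) pair detection, locus delimitation with a configurable
  flank.
- **B-locus discovery** — receptor location by annotation label, ORF
  enumeration in the 10-kb receptor flanks, and peptide filtering by the
  pheromone-precursor rules: (i) a C-terminal CaaX prenylation motif
  (C, two aliphatic residues from {A,V,L,I,G}, then X ∈ {A,S,M,Q,C}) and
  (ii) the conserved N-terminal AF and ER dipeptide signatures.
- **Allele typing** — Needleman–Wunsch global protein identity
  (BLOSUM62, gap open 10 / extend 1; identity = matches / alignment
  columns), exact-sequence allele classes (A1, A2, …, B1, B2, …), and
  composite genotypes such as `A1B2`.
- **Compatibility** — the tetrapolar rule over all strain pairs (bipolar
  mode available).
- **Locus microsynteny** — reciprocal-best pairing of locus genes,
  inversion and insertion calls (e.g. the matB2-style three-gene
  ZNF622/DBP10/STE12 insertion between *PhB* and *STE3*), and genome-wide
  strain-specific genes by the zero-reciprocal-match rule.
- **Synthetic genomes** — a deterministic simulator that plants all of the
  above (telomeres, loci, allele divergence, decoy ORFs) and emits a
  machine-readable truth manifest, so the whole pipeline is testable
  end-to-end without any download.

## Worked example

Generate the four-strain reference design and run the stages:

```sh
matmine simulate --seed 7 --outdir sim
matmine scan-telomeres --fasta sim/NS-27.fa --out tel.tsv
matmine find-mat-a --gff3 sim/NS-27.gff3 --fasta sim/NS-27.fa --out matA.json
matmine find-mat-b --gff3 sim/NS-29.gff3 --fasta sim/NS-29.fa --out matB.json
matmine genotype --proteins sim/NS-27.faa --proteins sim/NS-29.faa \
                 --proteins sim/NS-45.faa --proteins sim/NS-58.faa --out genotypes.tsv
matmine compat --genotypes genotypes.tsv --out matrix.tsv
```

which prints:

```text
24 telomeres, 12 telomere-to-telomere chromosomes
A locus: chr05:0-44991 (11 genes)
B locus: chr11:2769-59310; 1/167 ORFs pass the precursor filter; 3 inter-anchor genes
NS-27   A1B1
NS-29   A1B2
NS-45   A2B2
NS-58   A2B1
2 compatible pairs
```

Reading the output: every chromosome end of NS-27 carries a telomere
array (24 of 24); the A locus is the divergent HD1/HD2 pair on
chromosome 5; in NS-29 exactly one of the 167 ORFs found in the STE3
flanks survives the CaaX + AF/ER filter (the planted *PhB* precursor),
and three genes sit between the precursor and the receptor (the
matB2-style insertion). Allele typing groups NS-27/NS-29 (A1) against
NS-45/NS-58 (A2) at the A locus and NS-27/NS-58 (B1) against
NS-29/NS-45 (B2) at the B locus, and the tetrapolar rule leaves exactly
two compatible crosses:

```text
	NS-27	NS-29	NS-45	NS-58
NS-27	-	-	+	-
NS-29	-	-	-	+
NS-45	+	-	-	-
NS-58	-	+	-	-

# compatible pairs
# NS-27 x NS-45
# NS-29 x NS-58
```

`matmine run --strain NAME=genome.fa:annotation.gff3 ... --outdir out/`
executes every stage (including locus synteny and strain-specific gene
detection) and writes consolidated JSON + TSV reports. The same pipeline
is available as a library (`matmine.run_pipeline`).

## Layout

- `matmine.genomeio` — FASTA/GFF3 I/O, data model, CDS translation, N50/GC.
- `matmine.telomeres` — terminal monomer-array scanning.
- `matmine.hdlocus` / `matmine.prlocus` — A- and B-locus discovery.
- `matmine.alleles` / `matmine.compat` — identity, allele classes, genotypes,
  compatibility.
- `matmine.synteny` — locus gene pairing, inversions, strain-specific genes.
- `matmine.simulate` — synthetic genomes + truth manifest.
- `matmine.pipeline` / `matmine.cli` — orchestration and the `matmine`
  command.

See `docs/methods.md` for the modelling choices, parameter defaults and
limitations.
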