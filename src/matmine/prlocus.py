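"""B (pheromone/receptor) mating-type locus discovery.

The B locus couples a pheromone receptor (STE3, a seven-transmembrane
GPCR, found by annotation label) with one or more short lipopeptide
pheromone precursors.  Precursors are too short and divergent to be
annotated reliably, so they are recovered de novo: the 10-kb flanks of
each receptor are scanned for ORFs, the translated peptides are filtered
for (i) a C-terminal CaaX prenylation motif — Cys, two aliphatic residues
(A/V/L/I/G), then A/S/M/Q/C — and (ii) the conserved N-terminal AF and ER
dipeptide signatures within the first ``sig_window`` residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from matmine.genomeio import AnnotationSet, GeneModel, SequenceSet, revcomp
from matmine.hdlocus import LocusRegion

DEFAULT_RECEPTOR_KEYWORDS = ("pheromone receptor", "STE3")
DEFAULT_PRECURSOR_KEYWORDS = ("pheromone precursor", "PhB")
DEFAULT_FLANK = 10_000
DEFAULT_MIN_ORF_NT = 75
DEFAULT_SIG_WINDOW = 40
DEFAULT_B_FLANK = 25_000

CAAX_ALIPHATIC = frozenset("AVLIG")
CAAX_X = frozenset("ASMQC")

PEPTIDE_LENGTH_RANGE = (20, 120)   # outside -> flagged, never dropped

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class Orf:
    """A maximal ATG-to-stop open reading frame.

    ``span`` is on the scanned (flank) sequence; ``genomic_span`` on the
    chromosome.  ``nt_seq`` includes the stop codon; ``peptide`` excludes it.
    Both spans are forward-strand coordinates regardless of ORF strand.
    """

    strand: str
    span: tuple[int, int]
    nt_seq: str
    peptide: str
    genomic_span: Optional[tuple[int, int]] = None
    source: Optional[str] = None  # upstream_flank | downstream_flank


@dataclass
class PheromoneCall:
    """Per-rule evidence for one candidate pheromone-precursor peptide."""

    orf: Orf
    caax_ok: bool
    caax_residues: str
    nterm_ok: bool
    signature_positions: dict[str, Optional[int]]
    verdict: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class Flank:
    """A strand-agnostic genomic window beside a receptor gene."""

    side: str                     # upstream_flank | downstream_flank
    seq: str
    genomic_start: int            # offset of seq[0] on the chromosome


def find_receptors(annots: AnnotationSet,
                   keywords=DEFAULT_RECEPTOR_KEYWORDS) -> list[GeneModel]:
    """Genes whose functional labels mark them as pheromone receptors."""
    return [g for g in annots if g.matches_keywords(keywords)]


def extract_flanks(gene: GeneModel, genome: SequenceSet,
                   flank: int = DEFAULT_FLANK) -> tuple[Flank, Flank]:
    """The upstream and downstream genomic windows beside a gene.

    Windows are clipped at chromosome termini and reported with their
    genomic offsets; "upstream"/"downstream" refer to genomic coordinates,
    not gene strand.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom].seq
    up_start = max(0, gene.start - flank)
    down_end = min(len(chrom_seq), gene.end + flank)
    return (Flank("upstream_flank", chrom_seq[up_start:gene.start], up_start),
            Flank("downstream_flank", chrom_seq[gene.end:down_end], gene.end))


def find_orfs(seq: str, min_nt: int = DEFAULT_MIN_ORF_NT, strands: str = "both",
              longest_per_stop: bool = True) -> list[Orf]:
    """Enumerate maximal ATG-to-stop ORFs on one or both strands.

    An ORF runs from an ATG to the first in-frame stop (stop included in
    ``nt_seq`` and in the length test).  With ``longest_per_stop`` (the
    default) only the 5'-most ATG per stop is reported, as the NCBI ORF
    finder does; nested ATGs are reported when it is disabled.  Coordinates
    are forward-strand positions on ``seq`` for both strands.
    """
    if min_nt < 9 or min_nt % 3:
        raise ValueError("min_nt must be >= 9 and divisible by 3")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    n = len(seq)
    out: list[Orf] = []

    def _scan(s: str, strand: str) -> None:
        for frame in range(3):
            starts: list[int] = []
            for i in range(frame, len(s) - 2, 3):
                codon = s[i:i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in _STOPS:
                    chosen = starts if not longest_per_stop else starts[:1]
                    for a in chosen:
                        nt = s[a:i + 3]
                        if len(nt) >= min_nt:
                            pep = str(Seq(nt[:-3]).translate())
                            if strand == "+":
                                span = (a, i + 3)
                            else:
                                span = (n - (i + 3), n - a)
                            out.append(Orf(strand=strand, span=span,
                                           nt_seq=nt, peptide=pep))
                    starts = []

    _scan(seq, "+")
    if strands == "both":
        _scan(revcomp(seq), "-")
    out.sort(key=lambda o: (o.span, o.strand))
    return out


def classify_pheromone_precursor(peptide: str,
                                 sig_window: int = DEFAULT_SIG_WINDOW) -> PheromoneCall:
    """Apply the CaaX + N-terminal AF/ER filter to a candidate peptide.

    ``caax_ok``: the last four residues are C, aliphatic (A/V/L/I/G),
    aliphatic, then one of A/S/M/Q/C.  ``nterm_ok``: the dipeptides AF and
    ER each occur (either order) within the first ``sig_window`` residues.
    The verdict is the conjunction.  Peptides shorter than 4 residues fail
    with an explanatory flag; lengths outside the typical precursor range
    are flagged but still judged on the rules alone.
    """
    if not _AA_RE.match(peptide):
        raise ValueError("peptide contains non-amino-acid characters")
    orf = Orf(strand="+", span=(0, 0), nt_seq="", peptide=peptide)
    flags: list[str] = []
    if len(peptide) < 4:
        return PheromoneCall(orf=orf, caax_ok=False, caax_residues=peptide,
                             nterm_ok=False,
                             signature_positions={"AF": None, "ER": None},
                             verdict=False, flags=["too_short_for_caax"])
    tail = peptide[-4:]
    caax_ok = (tail[0] == "C" and tail[1] in CAAX_ALIPHATIC
               and tail[2] in CAAX_ALIPHATIC and tail[3] in CAAX_X)
    window = peptide[:sig_window]
    pos = {sig: (window.find(sig) if window.find(sig) >= 0 else None)
           for sig in ("AF", "ER")}
    nterm_ok = pos["AF"] is not None and pos["ER"] is not None
    lo, hi = PEPTIDE_LENGTH_RANGE
    if not lo <= len(peptide) <= hi:
        flags.append("atypical_length")
    return PheromoneCall(orf=orf, caax_ok=caax_ok, caax_residues=tail,
                         nterm_ok=nterm_ok, signature_positions=pos,
                         verdict=caax_ok and nterm_ok, flags=flags)


def scan_receptor_flanks(receptor: GeneModel, genome: SequenceSet,
                         flank: int = DEFAULT_FLANK,
                         min_orf_nt: int = DEFAULT_MIN_ORF_NT,
                         sig_window: int = DEFAULT_SIG_WINDOW) -> list[PheromoneCall]:
    """ORF-scan both receptor flanks and classify every translated peptide."""
    calls: list[PheromoneCall] = []
    for fl in extract_flanks(receptor, genome, flank):
        for orf in find_orfs(fl.seq, min_nt=min_orf_nt, strands="both"):
            orf.source = fl.side
            orf.genomic_span = (fl.genomic_start + orf.span[0],
                                fl.genomic_start + orf.span[1])
            call = classify_pheromone_precursor(orf.peptide, sig_window)
            call.orf = orf
            calls.append(call)
    return calls


def _distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def define_b_locus(receptor: GeneModel, calls: list[PheromoneCall],
                   annots: AnnotationSet, flank: int = DEFAULT_B_FLANK,
                   precursor_keywords=DEFAULT_PRECURSOR_KEYWORDS):
    """Delimit the B locus around a receptor and its nearest precursor.

    The second anchor is the verdict-true pheromone call nearest the
    receptor, or failing that an annotated precursor gene matched by label.
    Returns ``(LocusRegion, insertion_set)`` where the insertion set lists
    annotated genes lying strictly between the two anchors (the hallmark
    distinguishing an "inserted" B-locus architecture from the compact
    adjacent one).  With no precursor at all, a single-anchor region with a
    warning is returned.
    """
    true_calls = [c for c in calls if c.verdict and c.orf.genomic_span]
    anchor2: Optional[GeneModel] = None
    if true_calls:
        best = min(true_calls,
                   key=lambda c: _distance(c.orf.genomic_span,
                                           (receptor.start, receptor.end)))
        span = best.orf.genomic_span
        overlapping = [g for g in annots.overlapping(receptor.chrom, *span)
                       if g.strand == best.orf.strand and g.gene_id != receptor.gene_id]
        if overlapping:
            anchor2 = overlapping[0]
        else:
            anchor2 = GeneModel(gene_id=f"{receptor.gene_id}_precursor_orf",
                                chrom=receptor.chrom, start=span[0], end=span[1],
                                strand=best.orf.strand,
                                cds_segments=[span],
                                labels=["pheromone precursor (ORF call)"])
    else:
        labelled = [g for g in annots.on_chrom(receptor.chrom)
                    if g.matches_keywords(precursor_keywords)
                    and g.gene_id != receptor.gene_id]
        if labelled:
            anchor2 = min(labelled,
                          key=lambda g: _distance((g.start, g.end),
                                                  (receptor.start, receptor.end)))

    from matmine.hdlocus import define_locus  # local import avoids cycle at module load
    if anchor2 is None:
        region = define_locus([receptor], annots, flank=flank, locus_type="B")
        region.warnings.append("no pheromone precursor candidate found")
        return region, []
    region = define_locus([receptor, anchor2], annots, flank=flank, locus_type="B")
    lo = min(receptor.end, anchor2.end)
    hi = max(receptor.start, anchor2.start)
    insertion = [g for g in annots.on_chrom(receptor.chrom)
                 if g.start >= lo and g.end <= hi
                 and g.gene_id not in (receptor.gene_id, anchor2.gene_id)]
    return region, insertion
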