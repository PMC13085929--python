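"""A mating-type locus discovery: the divergent HD1/HD2 homeodomain pair.

In tetrapolar basidiomycetes the A locus encodes two homeodomain
transcription factors (HD1, HD2) transcribed divergently ("head-to-head":
adjacent genes on opposite strands with facing 5' ends).  Candidate HD
genes are recognised from functional annotation labels; the locus region
is the anchor pair extended by a configurable flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from matmine.genomeio import AnnotationSet, GeneModel

DEFAULT_HD_KEYWORDS = ("homeobox", "homeodomain", "HD1", "HD2")
DEFAULT_MAX_GAP = 10_000
DEFAULT_A_FLANK = 30_000


@dataclass
class HDPair:
    """A candidate divergently transcribed homeodomain gene pair."""

    hd1: GeneModel
    hd2: GeneModel
    intergenic_gap: int
    orientation: str  # head_to_head | other

    @property
    def chrom(self) -> str:
        return self.hd1.chrom

    @property
    def genes(self) -> tuple[GeneModel, GeneModel]:
        return (self.hd1, self.hd2)


@dataclass
class LocusRegion:
    """A typed genomic interval housing a MAT locus and its member genes."""

    locus_type: str               # A | B
    chrom: str
    span: tuple[int, int]
    member_genes: list[GeneModel] = field(default_factory=list)
    anchor_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def is_head_to_head(g1: GeneModel, g2: GeneModel, max_gap: int = DEFAULT_MAX_GAP) -> bool:
    """True iff two genes form a divergently transcribed, non-overlapping pair.

    The leftmost gene must lie on the minus strand and the rightmost on the
    plus strand (5' ends facing, transcription pointing apart), with an
    intergenic gap of at most ``max_gap``.  Symmetric in its arguments.
    """
    if g1.chrom != g2.chrom:
        raise ValueError(f"genes {g1.gene_id!r} and {g2.gene_id!r} are on different chromosomes")
    left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
    if left.end > right.start:          # overlapping intervals are rejected
        return False
    return (left.strand == "-" and right.strand == "+"
            and right.start - left.end <= max_gap)


def find_hd_pairs(annots: AnnotationSet, keywords=DEFAULT_HD_KEYWORDS,
                  max_gap: int = DEFAULT_MAX_GAP) -> list[HDPair]:
    """All divergent pairs among label-matched homeodomain candidate genes.

    Candidates are genes whose labels contain any keyword (case-insensitive
    substring).  Every unordered candidate pair passing
    :func:`is_head_to_head` is returned, sorted by intergenic gap ascending.
    """
    candidates = [g for g in annots if g.matches_keywords(keywords)]
    pairs = []
    for i, g1 in enumerate(candidates):
        for g2 in candidates[i + 1:]:
            if g1.chrom != g2.chrom:
                continue
            if is_head_to_head(g1, g2, max_gap):
                left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
                pairs.append(HDPair(hd1=left, hd2=right,
                                    intergenic_gap=right.start - left.end,
                                    orientation="head_to_head"))
    pairs.sort(key=lambda p: (p.intergenic_gap, p.hd1.gene_id))
    return pairs


def define_locus(anchors, annots: AnnotationSet, flank: int = DEFAULT_A_FLANK,
                 locus_type: str = "A") -> LocusRegion:
    """Delimit a locus region around anchor genes.

    ``anchors`` is an :class:`HDPair` or an iterable of :class:`GeneModel`.
    The span is the union of the anchor intervals extended by ``flank`` on
    both sides, clipped to the chromosome when its length is known; member
    genes are all annotated genes overlapping the span, in coordinate
    order, duplicate-free.
    """
    if isinstance(anchors, HDPair):
        anchor_genes = list(anchors.genes)
    else:
        anchor_genes = list(anchors)
    if not anchor_genes:
        raise ValueError("at least one anchor gene required")
    chroms = {g.chrom for g in anchor_genes}
    if len(chroms) > 1:
        raise ValueError(f"anchors span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    known = annots.chrom_lengths.get(chrom)
    if annots.chrom_lengths and known is None:
        raise ValueError(f"anchor chromosome {chrom!r} absent from genome")
    lo = max(0, min(g.start for g in anchor_genes) - flank)
    hi = max(g.end for g in anchor_genes) + flank
    if known is not None:
        hi = min(hi, known)
    members = annots.overlapping(chrom, lo, hi)
    seen, ordered = set(), []
    for g in members:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            ordered.append(g)
    return LocusRegion(locus_type=locus_type, chrom=chrom, span=(lo, hi),
                       member_genes=ordered,
                       anchor_ids=[g.gene_id for g in anchor_genes])
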