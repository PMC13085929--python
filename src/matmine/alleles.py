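"""Pairwise global protein identity, allele classing and mating genotypes.

Identity is computed from a Needleman-Wunsch global alignment (BLOSUM62,
gap open 10 / extend 1 by default) as matches over alignment columns; gap
columns count in the denominator unless ``count_gaps=False``.  Allele
classes follow the convention used for basidiomycete MAT loci: strains
with byte-identical marker proteins share an allele label, numbered in
first-seen strain order (A1, A2, ... / B1, B2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class IdentityResult:
    """Percent identity from one global pairwise protein alignment."""

    query_id: str
    subject_id: str
    identity_percent: float       # rounded to 2 decimals
    aligned_columns: int
    matches: int


@dataclass
class AlleleAssignment:
    """Per-strain allele labels at one MAT locus, with the identity evidence."""

    locus: str                    # A | B
    labels: dict[str, str]        # strain -> allele label
    classes: dict[str, list[str]] = field(default_factory=dict)  # label -> strains
    evidence: dict[tuple[str, str], IdentityResult] = field(default_factory=dict)


@dataclass(frozen=True)
class MatingGenotype:
    """A strain's composite tetrapolar mating type, e.g. A1B2."""

    strain: str
    a_allele: str
    b_allele: str

    @property
    def composite(self) -> str:
        return self.a_allele + self.b_allele


def _aligner(matrix: str = DEFAULT_MATRIX, gap_open: float = DEFAULT_GAP_OPEN,
             gap_extend: float = DEFAULT_GAP_EXTEND, mode: str = "global") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    return al


def global_identity(p1: str, p2: str, query_id: str = "query",
                    subject_id: str = "subject", matrix: str = DEFAULT_MATRIX,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND,
                    count_gaps: bool = True) -> IdentityResult:
    """Percent identity between two proteins under global alignment.

    Identity = matches / alignment columns, where gap columns are counted
    in the denominator (switchable with ``count_gaps``).  Among co-optimal
    alignments the aligner's first traceback is used, which is
    deterministic for fixed inputs and scoring.
    """
    if not p1 or not p2:
        raise ValueError("global_identity requires two non-empty sequences")
    if p1 == p2:
        n = len(p1)
        return IdentityResult(query_id, subject_id, 100.0, n, n)
    aln = _aligner(matrix, gap_open, gap_extend).align(p1, p2)[0]
    counts = aln.counts()
    matches = counts.identities
    columns = aln.length if count_gaps else counts.identities + counts.mismatches
    pct = round(100.0 * matches / columns, 2) if columns else 0.0
    return IdentityResult(query_id, subject_id, pct, columns, matches)


def assign_alleles(marker_proteins: dict[str, str], locus: str = "A",
                   with_evidence: bool = True) -> AlleleAssignment:
    """Group strains into allele classes by exact marker-protein identity.

    Labels are ``<locus>1``, ``<locus>2``, ... in order of first appearance
    over the input's strain order.  The full pairwise identity matrix is
    attached as evidence unless disabled.
    """
    if not marker_proteins:
        raise ValueError("at least one strain required")
    seq_to_label: dict[str, str] = {}
    labels: dict[str, str] = {}
    classes: dict[str, list[str]] = {}
    for strain, seq in marker_proteins.items():
        if seq not in seq_to_label:
            seq_to_label[seq] = f"{locus}{len(seq_to_label) + 1}"
        lab = seq_to_label[seq]
        labels[strain] = lab
        classes.setdefault(lab, []).append(strain)
    evidence = {}
    if with_evidence:
        strains = list(marker_proteins)
        for i, s1 in enumerate(strains):
            for s2 in strains[i + 1:]:
                res = global_identity(marker_proteins[s1], marker_proteins[s2],
                                      query_id=s1, subject_id=s2)
                evidence[(s1, s2)] = res
    return AlleleAssignment(locus=locus, labels=labels, classes=classes,
                            evidence=evidence)


def genotype_strains(a: AlleleAssignment, b: AlleleAssignment) -> list[MatingGenotype]:
    """Combine per-locus allele labels into composite mating genotypes."""
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        diff = sorted(sa.symmetric_difference(sb))
        raise ValueError(f"strain sets differ between loci: {diff}")
    return [MatingGenotype(strain=s, a_allele=a.labels[s], b_allele=b.labels[s])
            for s in a.labels]
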