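"""Locus-scale microsynteny and strain-specific gene detection.

MAT-locus neighbourhoods are compared gene-by-gene: reciprocal-best global
protein identity pairs genes across the two loci, gene-order reversal of
matched anchors calls inversions, and unmatched genes form per-locus
insertion sets.  Genome-wide strain-specific genes follow the
zero-reciprocal-match rule: a protein with no cross-proteome local-alignment
hit (identity >= 30% over >= 40% of the query) in either direction is
strain-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from matmine.alleles import _aligner, global_identity
from matmine.hdlocus import LocusRegion

DEFAULT_MATCH_THRESHOLD = 30.0   # cross-allele MAT genes diverge to ~35%
DEFAULT_HIT_IDENTITY = 30.0
DEFAULT_HIT_COVERAGE = 40.0


@dataclass
class GenePairing:
    """One gene-to-gene correspondence (or absence) between two loci."""

    gene_a: Optional[str]
    gene_b: Optional[str]
    identity_percent: Optional[float]
    relation: str                 # matched | inserted_in_a | inserted_in_b


@dataclass
class ArchitectureCall:
    """Ordered pairings plus inversion blocks and per-locus insertion sets."""

    pairings: list[GenePairing]
    inversions: list[list[GenePairing]] = field(default_factory=list)
    insertions_a: list[str] = field(default_factory=list)
    insertions_b: list[str] = field(default_factory=list)


def _locus_gene_ids(locus: LocusRegion) -> list[str]:
    return [g.gene_id for g in locus.member_genes]


def match_locus_genes(locus_a: LocusRegion, proteins_a: dict[str, str],
                      locus_b: LocusRegion, proteins_b: dict[str, str],
                      match_threshold: float = DEFAULT_MATCH_THRESHOLD) -> list[GenePairing]:
    """Pair genes of two loci by reciprocal-best global identity.

    All-vs-all identities are computed between member-gene proteins; pairs
    that are each other's best match and reach ``match_threshold`` become
    ``matched``; the rest are insertions.  Ties on identity break by gene
    id.  Missing proteins are an error naming the gene.
    """
    ids_a, ids_b = _locus_gene_ids(locus_a), _locus_gene_ids(locus_b)
    for gid, pool in [(g, proteins_a) for g in ids_a] + [(g, proteins_b) for g in ids_b]:
        if gid not in pool:
            raise KeyError(f"no protein provided for locus gene {gid!r}")
    ident: dict[tuple[str, str], float] = {}
    for ga in ids_a:
        for gb in ids_b:
            if proteins_a[ga] == proteins_b[gb]:
                ident[(ga, gb)] = 100.0
            else:
                ident[(ga, gb)] = global_identity(proteins_a[ga], proteins_b[gb],
                                                  ga, gb).identity_percent

    def best(gid: str, others: list[str], flip: bool) -> Optional[str]:
        scored = [(ident[(o, gid)] if flip else ident[(gid, o)], o) for o in others]
        scored.sort(key=lambda t: (-t[0], t[1]))
        return scored[0][1] if scored else None

    pairings: list[GenePairing] = []
    matched_b: set[str] = set()
    for ga in ids_a:
        gb = best(ga, ids_b, flip=False)
        if (gb is not None and ident[(ga, gb)] >= match_threshold
                and best(gb, ids_a, flip=True) == ga):
            pairings.append(GenePairing(ga, gb, ident[(ga, gb)], "matched"))
            matched_b.add(gb)
        else:
            pairings.append(GenePairing(ga, None, None, "inserted_in_a"))
    for gb in ids_b:
        if gb not in matched_b:
            pairings.append(GenePairing(None, gb, None, "inserted_in_b"))
    return pairings


def call_architecture(pairings: list[GenePairing], locus_a: LocusRegion,
                      locus_b: LocusRegion) -> ArchitectureCall:
    """Order matched pairs along locus A and call inversions and insertions.

    Matched pairs are sorted by locus-A coordinate; maximal runs (length
    >= 2) whose locus-B order is strictly decreasing are reported as
    inverted blocks.  Unmatched genes are grouped into per-locus insertion
    sets in coordinate order.
    """
    pos_a = {g.gene_id: i for i, g in enumerate(locus_a.member_genes)}
    pos_b = {g.gene_id: i for i, g in enumerate(locus_b.member_genes)}
    matched = [p for p in pairings if p.relation == "matched"]
    matched.sort(key=lambda p: pos_a[p.gene_a])
    inversions: list[list[GenePairing]] = []
    run: list[GenePairing] = []
    for p in matched:
        if run and pos_b[p.gene_b] < pos_b[run[-1].gene_b]:
            run.append(p)
        else:
            if len(run) >= 2:
                inversions.append(run)
            run = [p]
    if len(run) >= 2:
        inversions.append(run)
    ins_a = sorted((p.gene_a for p in pairings if p.relation == "inserted_in_a"),
                   key=lambda g: pos_a[g])
    ins_b = sorted((p.gene_b for p in pairings if p.relation == "inserted_in_b"),
                   key=lambda g: pos_b[g])
    ordered = matched + [p for p in pairings if p.relation != "matched"]
    return ArchitectureCall(pairings=ordered, inversions=inversions,
                            insertions_a=ins_a, insertions_b=ins_b)


def _local_hit(q: str, s: str, aligner, min_identity: float,
               min_coverage: float) -> tuple[bool, bool]:
    """(hit for query q, hit for subject s) under the identity+coverage rule."""
    if q == s:
        return True, True
    aln = aligner.align(q, s)
    if len(aln) == 0:
        return False, False
    a = aln[0]
    counts = a.counts()
    if a.length == 0:
        return False, False
    # gap columns count in the denominator: discriminates true homology
    # from the gappy chance alignments an identity-only ratio admits
    ident = 100.0 * counts.identities / a.length
    q_res = sum(e - s0 for s0, e in a.aligned[0])
    s_res = sum(e - s0 for s0, e in a.aligned[1])
    ok = ident >= min_identity
    return (ok and 100.0 * q_res / len(q) >= min_coverage,
            ok and 100.0 * s_res / len(s) >= min_coverage)


def find_strain_specific_genes(proteome_a: dict[str, str], proteome_b: dict[str, str],
                               min_identity: float = DEFAULT_HIT_IDENTITY,
                               min_coverage: float = DEFAULT_HIT_COVERAGE
                               ) -> tuple[set[str], set[str]]:
    """Genes with zero reciprocal cross-proteome matches, per proteome.

    A hit is a cross-proteome local alignment (BLOSUM62, open 10 / extend
    1) with identity >= ``min_identity`` percent over >= ``min_coverage``
    percent of the gene's length.  A gene is strain-specific when it has no
    hit in either direction.  Exact sequence matches short-circuit without
    alignment.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    aligner = _aligner(mode="local")
    seqs_b = {}
    for gid, seq in proteome_b.items():
        seqs_b.setdefault(seq, []).append(gid)
    hit_a: set[str] = set()
    hit_b: set[str] = set()
    for ga, qa in proteome_a.items():
        if qa in seqs_b:                      # identical sequence: mutual hit
            hit_a.add(ga)
            hit_b.update(seqs_b[qa])
            continue
        for gb, qb in proteome_b.items():
            ha, hb = _local_hit(qa, qb, aligner, min_identity, min_coverage)
            if ha:
                hit_a.add(ga)
            if hb:
                hit_b.add(gb)
    # second pass: b genes still unhit may only resemble a-proteins whose
    # alignments were short-circuited above; check them as queries
    for gb in set(proteome_b) - hit_b:
        qb = proteome_b[gb]
        for ga, qa in proteome_a.items():
            hb, ha = _local_hit(qb, qa, aligner, min_identity, min_coverage)
            if hb:
                hit_b.add(gb)
            if ha:
                hit_a.add(ga)
        # no break: full scan keeps hit evidence symmetric
    return (set(proteome_a) - hit_a, set(proteome_b) - hit_b)
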