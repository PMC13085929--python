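"""Telomeric repeat-array detection at chromosome termini.

Tremellaceous chromosome ends carry exact tandem arrays of a short monomer:
(CCCCCTAA)n at the 5' terminus and its reverse complement (TTAGGGGG)n at
the 3' terminus.  Detection is exact-tandem: a terminus is called
telomeric when a maximal run of >= ``min_copies`` exact monomer copies
starts (5') or ends (3') within ``max_offset`` bp of the terminus.
Degenerate variants and monomer rotations are deliberately not matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from matmine.genomeio import SequenceSet

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

DEFAULT_MONOMER_5 = "CCCCCTAA"
DEFAULT_MONOMER_3 = "TTAGGGGG"
DEFAULT_MIN_COPIES = 3
DEFAULT_MAX_OFFSET = 1000


@dataclass(frozen=True)
class TelomereArray:
    """A maximal exact tandem run of a telomere monomer at one terminus."""

    chrom: str
    end: str                      # five_prime | three_prime
    monomer: str
    copies: int
    span: tuple[int, int]         # 0-based half-open on the chromosome
    offset_from_terminus: int


@dataclass
class TelomereReport:
    """Per-chromosome telomere calls plus genome-wide totals."""

    arrays: dict[str, dict[str, Optional[TelomereArray]]] = field(default_factory=dict)

    @property
    def total_telomeres(self) -> int:
        return sum(1 for ends in self.arrays.values() for a in ends.values() if a)

    @property
    def t2t_chromosomes(self) -> int:
        """Chromosomes with telomeres detected at both ends."""
        return sum(1 for ends in self.arrays.values()
                   if ends.get(FIVE_PRIME) and ends.get(THREE_PRIME))

    def to_rows(self) -> list[dict]:
        rows = []
        for chrom, ends in self.arrays.items():
            for which in (FIVE_PRIME, THREE_PRIME):
                arr = ends.get(which)
                if arr:
                    rows.append(dict(chrom=chrom, end=which, start=arr.span[0],
                                     end_coord=arr.span[1], copies=arr.copies,
                                     offset=arr.offset_from_terminus))
        return rows


def scan_end(seq: str, monomer: str, min_copies: int = DEFAULT_MIN_COPIES,
             max_offset: int = DEFAULT_MAX_OFFSET, which_end: str = FIVE_PRIME,
             chrom: str = "") -> Optional[TelomereArray]:
    """Find the terminal telomere array at one end of a chromosome sequence.

    Returns the qualifying maximal exact tandem run of ``monomer`` nearest
    the requested terminus, or ``None``.  A run qualifies when its copy
    count is >= ``min_copies`` and its terminus-proximal boundary lies
    within ``max_offset`` bp of the chromosome end.
    """
    if len(monomer) < 4:
        raise ValueError("monomer length must be >= 4")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    if not re.fullmatch(r"[ACGT]+", monomer):
        raise ValueError(f"monomer {monomer!r} contains non-ACGT characters")
    if which_end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"which_end must be {FIVE_PRIME!r} or {THREE_PRIME!r}")

    m = len(monomer)
    runs = []
    for match in re.finditer(f"(?:{monomer})+", seq):
        copies = (match.end() - match.start()) // m
        if copies >= min_copies:
            runs.append((match.start(), match.start() + copies * m, copies))
    if not runs:
        return None

    if which_end == FIVE_PRIME:
        runs = [r for r in runs if r[0] <= max_offset]
        if not runs:
            return None
        start, end, copies = min(runs, key=lambda r: r[0])
        offset = start
    else:
        runs = [r for r in runs if len(seq) - r[1] <= max_offset]
        if not runs:
            return None
        start, end, copies = max(runs, key=lambda r: r[1])
        offset = len(seq) - end
    return TelomereArray(chrom=chrom, end=which_end, monomer=monomer,
                         copies=copies, span=(start, end),
                         offset_from_terminus=offset)


def scan_genome(seqs: SequenceSet, monomer5: str = DEFAULT_MONOMER_5,
                monomer3: str = DEFAULT_MONOMER_3,
                min_copies: int = DEFAULT_MIN_COPIES,
                max_offset: int = DEFAULT_MAX_OFFSET) -> TelomereReport:
    """Scan both ends of every chromosome for telomere arrays."""
    report = TelomereReport()
    for rec in seqs:
        report.arrays[rec.id] = {
            FIVE_PRIME: scan_end(rec.seq, monomer5, min_copies, max_offset,
                                 FIVE_PRIME, chrom=rec.id),
            THREE_PRIME: scan_end(rec.seq, monomer3, min_copies, max_offset,
                                  THREE_PRIME, chrom=rec.id),
        }
    return report
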