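"""Tetrapolar compatibility: two monokaryons mate only when both MAT loci differ.

In a tetrapolar mating system sexual compatibility requires different
alleles at the A locus AND at the B locus; a bipolar mode (A only) is
provided for reuse with bipolar species.  Unknown alleles propagate as
indeterminate rather than silently compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from matmine.alleles import MatingGenotype


@dataclass
class CompatibilityMatrix:
    """Symmetric pairwise compatibility with a false diagonal."""

    strains: list[str]
    matrix: dict[tuple[str, str], bool | None] = field(default_factory=dict)
    compatible_pairs: list[tuple[str, str]] = field(default_factory=list)
    indeterminate_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_compatible(self) -> int:
        return len(self.compatible_pairs)

    def __getitem__(self, pair: tuple[str, str]) -> bool | None:
        s1, s2 = pair
        if s1 == s2:
            return False
        return self.matrix[tuple(sorted((s1, s2)))]


def compatible(g1: MatingGenotype, g2: MatingGenotype, bipolar: bool = False) -> bool | None:
    """Whether two genotypes can mate (tetrapolar rule by default).

    Returns ``None`` (indeterminate) when an allele needed by the rule is
    missing; self-crosses and same-strain comparisons are never compatible.
    """
    if g1.strain == g2.strain:
        return False
    alleles = [(g1.a_allele, g2.a_allele)]
    if not bipolar:
        alleles.append((g1.b_allele, g2.b_allele))
    for x, y in alleles:
        if not x or not y:
            return None
    return all(x != y for x, y in alleles)


def compatibility_matrix(genotypes: list[MatingGenotype],
                         bipolar: bool = False) -> CompatibilityMatrix:
    """Evaluate all unordered strain pairs under the compatibility rule."""
    if len(genotypes) < 2:
        raise ValueError("at least two strains required")
    names = [g.strain for g in genotypes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate strain names: {dupes}")
    cm = CompatibilityMatrix(strains=names)
    for g1, g2 in combinations(genotypes, 2):
        verdict = compatible(g1, g2, bipolar=bipolar)
        key = tuple(sorted((g1.strain, g2.strain)))
        cm.matrix[key] = verdict
        if verdict is None:
            cm.indeterminate_pairs.append((g1.strain, g2.strain))
        elif verdict:
            cm.compatible_pairs.append((g1.strain, g2.strain))
    return cm
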