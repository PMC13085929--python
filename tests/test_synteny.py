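"""Locus microsynteny: gene pairing, inversions, strain-specific genes."""

import numpy as np
import pytest

from matmine.alleles import global_identity
from matmine.genomeio import GeneModel
from matmine.hdlocus import LocusRegion
from matmine.simulate import mutate_protein, random_protein
from matmine.synteny import (
    call_architecture,
    find_strain_specific_genes,
    match_locus_genes,
)


def _locus(genes, chrom="chr1", locus_type="A"):
    return LocusRegion(locus_type=locus_type, chrom=chrom,
                       span=(genes[0].start, genes[-1].end),
                       member_genes=genes, anchor_ids=[genes[0].gene_id])


def _genes(prefix, n, strands=None):
    out = []
    for i in range(n):
        s, e = 1000 * i, 1000 * i + 600
        out.append(GeneModel(f"{prefix}{i}", "chr1", s, e,
                             (strands[i] if strands else "+"), [(s, e)]))
    return out


def _brute_reciprocal_best(pa, pb, thr):
    """Independent oracle: a pair is matched iff each is the other's
    unique-by-tie-break best and identity reaches the threshold."""
    ident = {(a, b): global_identity(pa[a], pb[b]).identity_percent
             for a in pa for b in pb}

    def best(x, pool, getter):
        return min(pool, key=lambda y: (-getter(y), y))

    matched = set()
    for a in pa:
        b = best(a, pb, lambda y: ident[(a, y)])
        if ident[(a, b)] >= thr and best(b, pa, lambda x: ident[(x, b)]) == a:
            matched.add((a, b))
    return matched


class TestMatchLocusGenes:
    def test_identical_loci_all_matched_at_100(self):
        rng = np.random.default_rng(30)
        peps = {f"g{i}": random_protein(rng, 120) for i in range(4)}
        ga, gb = _genes("a", 4), _genes("b", 4)
        pa = {g.gene_id: peps[f"g{i}"] for i, g in enumerate(ga)}
        pb = {g.gene_id: peps[f"g{i}"] for i, g in enumerate(gb)}
        pairings = match_locus_genes(_locus(ga), pa, _locus(gb), pb)
        assert all(p.relation == "matched" and p.identity_percent == 100.0
                   for p in pairings)

    def test_agrees_with_brute_force_reciprocal_best(self):
        rng = np.random.default_rng(31)
        base = [random_protein(rng, 100) for _ in range(5)]
        ga = _genes("a", 5)
        gb = _genes("b", 6)
        pa = {g.gene_id: base[i] for i, g in enumerate(ga)}
        pb = {}
        for i, g in enumerate(gb[:5]):
            pb[g.gene_id] = mutate_protein(base[i], 70, seed=100 + i)
        pb[gb[5].gene_id] = random_protein(rng, 100)      # unrelated extra
        pairings = match_locus_genes(_locus(ga), pa, _locus(gb), pb,
                                     match_threshold=30)
        got = {(p.gene_a, p.gene_b) for p in pairings if p.relation == "matched"}
        assert got == _brute_reciprocal_best(pa, pb, 30)

    def test_symmetry_under_locus_swap(self):
        rng = np.random.default_rng(32)
        base = [random_protein(rng, 90) for _ in range(3)]
        ga, gb = _genes("a", 3), _genes("b", 4)
        pa = {g.gene_id: base[i] for i, g in enumerate(ga)}
        pb = {g.gene_id: (base[i] if i < 3 else random_protein(rng, 90))
              for i, g in enumerate(gb)}
        fwd = match_locus_genes(_locus(ga), pa, _locus(gb), pb)
        rev = match_locus_genes(_locus(gb), pb, _locus(ga), pa)
        fwd_matched = {(p.gene_a, p.gene_b) for p in fwd if p.relation == "matched"}
        rev_matched = {(p.gene_b, p.gene_a) for p in rev if p.relation == "matched"}
        assert fwd_matched == rev_matched
        assert ({p.gene_b for p in fwd if p.relation == "inserted_in_b"}
                == {p.gene_a for p in rev if p.relation == "inserted_in_a"})

    def test_partition_property(self):
        rng = np.random.default_rng(33)
        ga, gb = _genes("a", 3), _genes("b", 5)
        pa = {g.gene_id: random_protein(rng, 80) for g in ga}
        pb = {g.gene_id: random_protein(rng, 80) for g in gb}
        pairings = match_locus_genes(_locus(ga), pa, _locus(gb), pb)
        seen_a = [p.gene_a for p in pairings if p.gene_a]
        seen_b = [p.gene_b for p in pairings if p.gene_b]
        assert sorted(seen_a) == sorted(g.gene_id for g in ga)
        assert sorted(seen_b) == sorted(g.gene_id for g in gb)

    def test_missing_protein_names_gene(self):
        ga, gb = _genes("a", 2), _genes("b", 2)
        pa = {"a0": "MKV" * 30}           # a1 missing
        pb = {g.gene_id: "MKV" * 30 for g in gb}
        with pytest.raises(KeyError, match="a1"):
            match_locus_genes(_locus(ga), pa, _locus(gb), pb)


class TestArchitecture:
    def test_collinear_loci_have_no_inversions(self):
        rng = np.random.default_rng(34)
        peps = [random_protein(rng, 100) for _ in range(4)]
        ga, gb = _genes("a", 4), _genes("b", 4)
        pa = {g.gene_id: peps[i] for i, g in enumerate(ga)}
        pb = {g.gene_id: peps[i] for i, g in enumerate(gb)}
        la, lb = _locus(ga), _locus(gb)
        call = call_architecture(match_locus_genes(la, pa, lb, pb), la, lb)
        assert call.inversions == []

    def test_planted_two_gene_inverted_block(self):
        rng = np.random.default_rng(35)
        peps = [random_protein(rng, 100) for _ in range(4)]
        ga, gb = _genes("a", 4), _genes("b", 4)
        order_b = [0, 2, 1, 3]            # genes 1 and 2 swap positions in b
        pa = {g.gene_id: peps[i] for i, g in enumerate(ga)}
        pb = {g.gene_id: peps[order_b[i]] for i, g in enumerate(gb)}
        la, lb = _locus(ga), _locus(gb)
        call = call_architecture(match_locus_genes(la, pa, lb, pb), la, lb)
        assert len(call.inversions) == 1
        assert [p.gene_a for p in call.inversions[0]] == ["a1", "a2"]

    def test_matb_comparison_reports_inter_anchor_insertion(self, strain_set,
                                                            pipeline_result):
        # compact (matB1-like) vs inserted (matB2-like) B locus between strains
        _, manifest = strain_set
        call = pipeline_result.synteny[("NS-27", "NS-29", "B")]
        inserted = set(manifest.strains["NS-29"]["b_locus"]["insertion_genes"])
        assert inserted <= set(call.insertions_b)
        assert not any(g in call.insertions_a for g in inserted)

    def test_allele_markers_still_match_across_divergent_loci(self, pipeline_result):
        # cross-allele markers (STE3 at ~35% identity) stay paired, as the
        # 30% match threshold intends
        call = pipeline_result.synteny[("NS-27", "NS-45", "B")]
        matched = {(p.gene_a, p.gene_b) for p in call.pairings
                   if p.relation == "matched"}
        assert ("NS-27_STE3", "NS-45_STE3") in matched
        assert ("NS-27_PhB", "NS-45_PhB") in matched


class TestStrainSpecific:
    def test_identical_proteomes_have_none(self):
        rng = np.random.default_rng(36)
        p = {f"g{i}": random_protein(rng, 150) for i in range(8)}
        assert find_strain_specific_genes(p, dict(p)) == (set(), set())

    def test_planted_random_protein_is_the_only_specific_gene(self):
        rng = np.random.default_rng(37)
        pa = {f"g{i}": random_protein(rng, 150) for i in range(8)}
        pb = dict(pa)
        pb["unique"] = random_protein(rng, 300)
        sa, sb = find_strain_specific_genes(pa, pb)
        assert sa == set() and sb == {"unique"}

    def test_diverged_allele_is_not_specific(self):
        rng = np.random.default_rng(38)
        pa = {f"g{i}": random_protein(rng, 150) for i in range(5)}
        pb = dict(pa)
        pb["g0"] = mutate_protein(pa["g0"], 40, seed=9)   # far allele, still a hit
        sa, sb = find_strain_specific_genes(pa, pb)
        assert sa == set() and sb == set()

    def test_empty_proteome_is_error(self):
        with pytest.raises(ValueError):
            find_strain_specific_genes({}, {"g": "MKV"})

    def test_insertion_block_is_strain_specific_in_reference_design(
            self, strain_set, pipeline_result):
        _, manifest = strain_set
        sa, sb = pipeline_result.strain_specific[("NS-27", "NS-45")]
        assert sa == set()
        assert sb == set(manifest.strains["NS-45"]["b_locus"]["insertion_genes"])
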