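"""B-locus discovery: ORF enumeration and the pheromone-precursor filter."""

from itertools import product

import numpy as np
import pytest

from matmine.genomeio import GeneModel, SequenceRecord, SequenceSet, revcomp
from matmine.prlocus import (
    CAAX_ALIPHATIC,
    CAAX_X,
    classify_pheromone_precursor,
    define_b_locus,
    extract_flanks,
    find_orfs,
    find_receptors,
    scan_receptor_flanks,
)

_STOPS = {"TAA", "TAG", "TGA"}


def _orf_oracle(seq, min_nt):
    """Six-frame brute force: first ATG after each in-frame stop, extended
    to the next in-frame stop (independent of the scanner's bookkeeping)."""
    found = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            j = i - 3                      # longest-per-stop: no ATG upstream
            blocked = False
            while j >= 0:
                c = s[j:j + 3]
                if c in _STOPS:
                    break
                if c == "ATG":
                    blocked = True
                    break
                j -= 3
            if blocked:
                continue
            k = i + 3
            while k + 3 <= n and s[k:k + 3] not in _STOPS:
                k += 3
            if k + 3 > n:
                continue                   # no stop: not an ORF
            if k + 3 - i >= min_nt:
                span = (i, k + 3) if strand == "+" else (n - (k + 3), n - i)
                found.add((strand, span))
    return found


class TestFindOrfs:
    def test_minimal_orf_hand_translation(self):
        orfs = find_orfs("ATGAAATAG", min_nt=9)
        fwd = [o for o in orfs if o.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].peptide == "MK"
        assert fwd[0].span == (0, 9)
        assert fwd[0].nt_seq == "ATGAAATAG"

    def test_no_atg_no_orfs(self):
        assert find_orfs("C" * 120, min_nt=30) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_six_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        got = {(o.strand, o.span) for o in find_orfs(seq, min_nt=75)}
        assert got == _orf_oracle(seq, 75)

    def test_strand_consistency_under_revcomp(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        n = len(seq)
        fwd = {(o.strand, o.span, o.peptide) for o in find_orfs(seq, min_nt=75)}
        flipped = {({"+": "-", "-": "+"}[s], (n - e, n - a), p)
                   for s, (a, e), p in fwd}
        rc = {(o.strand, o.span, o.peptide) for o in find_orfs(revcomp(seq), min_nt=75)}
        assert rc == flipped

    def test_nested_atg_reported_when_rule_disabled(self):
        seq = "ATGAAAATGAAATAG"            # two in-frame ATGs, one stop
        longest = find_orfs(seq, min_nt=9)
        both = find_orfs(seq, min_nt=9, longest_per_stop=False)
        assert len(longest) == 1 and longest[0].span == (0, 15)
        assert {o.span for o in both} == {(0, 15), (6, 15)}

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_orfs("ATG", min_nt=20)
        with pytest.raises(ValueError):
            find_orfs("ATG", min_nt=75, strands="reverse")


class TestClassify:
    def test_passing_peptide(self):
        call = classify_pheromone_precursor("MAFSERLLQGGSNDCVIA")
        assert call.caax_ok and call.nterm_ok and call.verdict
        assert call.caax_residues == "CVIA"
        assert call.signature_positions == {"AF": 1, "ER": 4}

    def test_bad_terminal_x_fails_caax_only(self):
        call = classify_pheromone_precursor("MAFSERLLQGGSNDCVIR")
        assert not call.caax_ok and call.nterm_ok and not call.verdict

    def test_missing_af_fails_nterm_only(self):
        call = classify_pheromone_precursor("MSSQRLLQGGSNDCVIA")
        assert call.caax_ok and not call.nterm_ok and not call.verdict

    def test_signatures_must_fall_inside_window(self):
        pep = "M" * 50 + "AFER" + "M" * 10 + "CVIA"
        assert not classify_pheromone_precursor(pep, sig_window=40).nterm_ok
        assert classify_pheromone_precursor(pep, sig_window=60).nterm_ok

    def test_short_peptide_fails_with_reason(self):
        call = classify_pheromone_precursor("MKV")
        assert not call.verdict and "too_short_for_caax" in call.flags

    def test_illegal_residue_is_error(self):
        with pytest.raises(ValueError):
            classify_pheromone_precursor("MAFSER*CVIA")

    def test_agrees_with_set_membership_oracle_small_alphabet(self):
        # exhaustive over all peptides of length 4-6 from a 6-letter alphabet
        # that exercises every rule set (C, aliphatic, X-set, and F/E/R for
        # the N-terminal signatures)
        alphabet = "CAVSFE"
        for length in (4, 5, 6):
            for tup in product(alphabet, repeat=length):
                pep = "".join(tup)
                want_caax = (pep[-4] == "C" and pep[-3] in CAAX_ALIPHATIC
                             and pep[-2] in CAAX_ALIPHATIC and pep[-1] in CAAX_X)
                want_nterm = "AF" in pep[:40] and "ER" in pep[:40]
                call = classify_pheromone_precursor(pep)
                assert call.caax_ok == want_caax
                assert call.nterm_ok == want_nterm
                assert call.verdict == (want_caax and want_nterm)


class TestFlanks:
    def test_clipped_upstream(self):
        genome = SequenceSet([SequenceRecord("chr1", "A" * 10_000)])
        gene = GeneModel("g", "chr1", 50, 150, "+", [(50, 150)])
        up, down = extract_flanks(gene, genome, flank=10_000)
        assert len(up.seq) == 50 and up.genomic_start == 0
        assert len(down.seq) == 9850 and down.genomic_start == 150

    def test_zero_flank_empty(self):
        genome = SequenceSet([SequenceRecord("chr1", "A" * 1000)])
        gene = GeneModel("g", "chr1", 400, 600, "-", [(400, 600)])
        up, down = extract_flanks(gene, genome, flank=0)
        assert up.seq == "" and down.seq == ""


class TestBLocus:
    def test_receptor_found_by_label(self, strain_set):
        strains, manifest = strain_set
        for sid, data in strains.items():
            receptors = find_receptors(data.annots)
            assert [g.gene_id for g in receptors] == [manifest.strains[sid]["b_locus"]["ste3"]]

    def test_adjacent_architecture_has_empty_insertion_set(self, strain_set):
        strains, manifest = strain_set
        self._check(strains, manifest, "NS-27", [])

    def test_inserted_architecture_reports_three_genes(self, strain_set):
        strains, manifest = strain_set
        truth = manifest.strains["NS-29"]["b_locus"]
        self._check(strains, manifest, "NS-29", truth["insertion_genes"])

    def _check(self, strains, manifest, sid, expected_insertion):
        data = strains[sid]
        truth = manifest.strains[sid]["b_locus"]
        receptor = find_receptors(data.annots)[0]
        calls = scan_receptor_flanks(receptor, data.genome)
        region, insertion = define_b_locus(receptor, calls, data.annots)
        assert truth["phb"] in region.anchor_ids
        assert truth["ste3"] in region.anchor_ids
        assert [g.gene_id for g in insertion] == expected_insertion

    def test_planted_precursor_recovered_as_verdict_true_orf(self, strain_set):
        strains, manifest = strain_set
        for sid, data in strains.items():
            receptor = find_receptors(data.annots)[0]
            calls = scan_receptor_flanks(receptor, data.genome)
            true_calls = [c for c in calls if c.verdict]
            assert len(true_calls) == 1
            phb = manifest.strains[sid]["b_locus"]["phb"]
            assert true_calls[0].orf.peptide == data.proteins[phb].seq

    def test_verdict_true_calls_lie_within_scan_flank(self, strain_set):
        strains, _ = strain_set
        data = strains["NS-45"]
        receptor = find_receptors(data.annots)[0]
        for call in scan_receptor_flanks(receptor, data.genome, flank=10_000):
            if call.verdict:
                s, e = call.orf.genomic_span
                assert receptor.start - 10_000 <= s and e <= receptor.end + 10_000
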