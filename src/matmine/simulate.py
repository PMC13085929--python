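"""Synthetic multi-strain fungal genome generator with a ground-truth manifest.

Emulates the genome shape of a tetrapolar tremellaceous monokaryon set:
12 haploid chromosomes flanked by exact telomere-monomer arrays
((CCCCCTAA)n at 5', (TTAGGGGG)n at 3'), an A mating-type locus (divergent
HD1/HD2 homeodomain pair) on chromosome 5, a B mating-type locus
(pheromone precursor PhB + receptor STE3) on chromosome 11 with either a
compact "adjacent" architecture or an "inserted" one carrying three extra
genes (ZNF622/DBP10/STE12) between the anchors, and controlled inter-allele
protein divergence (HD ~78%, PhB ~77%, STE3 ~35% identity by default).

Every strain shares one background layout (genes, spacers, introns), so
cross-strain differences are exactly the planted ones: allele-variant
marker proteins and the B-locus insertion block.  Decoy ORFs that fail
exactly one pheromone-precursor rule are planted in the receptor flanks as
specificity controls.  All randomness flows from a single seed; identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from matmine.genomeio import (
    AnnotationSet,
    GeneModel,
    SequenceRecord,
    SequenceSet,
    extract_protein,
    revcomp,
    write_fasta,
    write_gff3,
)
from matmine.prlocus import classify_pheromone_precursor
from matmine.telomeres import DEFAULT_MONOMER_3, DEFAULT_MONOMER_5

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_GC = 53.65          # percent; four-strain assembly average
DEFAULT_N_CHROMS = 12
DEFAULT_TELOMERE_COPIES = 5
A_CHROM_INDEX = 4           # "chromosome 5"
B_CHROM_INDEX = 10          # "chromosome 11"

# default inter-allele identity targets (percent), matching the divergence
# regime of reported basidiomycete MAT alleles: conserved HD/PhB vs a
# highly diverged receptor
DEFAULT_HD1_IDENTITY = 78.30
DEFAULT_HD2_IDENTITY = 77.22
DEFAULT_PHB_IDENTITY = 76.72
DEFAULT_STE3_IDENTITY = 35.10

_STOP_CODONS = ("TAA", "TAG", "TGA")

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_FOR.setdefault(aa, []).append(codon)

_NEUTRAL_LABELS = (
    "hypothetical protein", "ATP-binding cassette transporter",
    "cytochrome P450 monooxygenase", "glycoside hydrolase",
    "mitochondrial carrier protein", "serine protease",
    "zinc-binding dehydrogenase", "ankyrin repeat protein",
    "glutathione S-transferase", "major facilitator superfamily transporter",
)

# last residue of background proteins is drawn from this set so that no
# annotated neighbour can satisfy the CaaX terminal rule by accident
_SAFE_TERMINAL = "DEFHKNPRTWY"


@dataclass
class StrainDesign:
    """Planted genotype and B-locus architecture for one synthetic strain."""

    strain_name: str
    a_allele: str = "A1"
    b_allele: str = "B1"
    b_architecture: str = "adjacent"          # adjacent | inserted
    hd1_identity: float = DEFAULT_HD1_IDENTITY
    hd2_identity: float = DEFAULT_HD2_IDENTITY
    phb_identity: float = DEFAULT_PHB_IDENTITY
    ste3_identity: float = DEFAULT_STE3_IDENTITY

    def __post_init__(self):
        if self.b_architecture not in ("adjacent", "inserted"):
            raise ValueError(f"unknown b_architecture {self.b_architecture!r}")
        for t in (self.hd1_identity, self.hd2_identity,
                  self.phb_identity, self.ste3_identity):
            if not 20 <= t <= 100:
                raise ValueError(f"target identity {t} outside [20,100]")


def default_design() -> list[StrainDesign]:
    """The four-strain reference design: genotypes A1B1/A1B2/A2B2/A2B1.

    Strains 2 and 3 (the B2 carriers) receive the inserted B-locus
    architecture; the compatible crosses are strain1 x strain3 and
    strain2 x strain4.
    """
    return [
        StrainDesign("NS-27", "A1", "B1", "adjacent"),
        StrainDesign("NS-29", "A1", "B2", "inserted"),
        StrainDesign("NS-45", "A2", "B2", "inserted"),
        StrainDesign("NS-58", "A2", "B1", "adjacent"),
    ]


@dataclass
class StrainData:
    """In-memory genome + annotation + proteome for one synthetic strain."""

    name: str
    genome: SequenceSet
    annots: AnnotationSet
    proteins: SequenceSet


@dataclass
class TruthManifest:
    """Ground truth for a generated strain set, the recovery-test surface."""

    seed: int
    scale: str
    strains: dict[str, dict] = field(default_factory=dict)
    expected_compatible_pairs: list[tuple[str, str]] = field(default_factory=list)
    marker_identity_targets: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scale": self.scale,
            "strains": self.strains,
            "expected_compatible_pairs": [list(p) for p in self.expected_compatible_pairs],
            "marker_identity_targets": self.marker_identity_targets,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequence-level primitives

def _derived_seed(master_seed: int, tag: str) -> int:
    return (int(master_seed) * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A random protein: Met start, CaaX-safe terminal residue."""
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
    tail = str(rng.choice(list(_SAFE_TERMINAL)))
    return "M" + body + tail


def random_dna(rng: np.random.Generator, length: int, gc: float = DEFAULT_GC) -> str:
    """i.i.d. nucleotides at the requested GC percentage."""
    g = gc / 200.0
    probs = [0.5 - g, g, g, 0.5 - g]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def reverse_translate(pep: str, seed: int) -> str:
    """A CDS encoding ``pep``: uniform synonymous codons plus a stop codon.

    Deterministic per seed; ``translate(reverse_translate(p))`` strips the
    stop and returns ``p``.
    """
    rng = np.random.default_rng(seed)
    codons = []
    for aa in pep:
        if aa not in CODONS_FOR:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def mutate_protein(seq: str, target_identity: float, seed: int,
                   frozen: frozenset | set = frozenset()) -> str:
    """Substitute random positions until positional identity first drops
    to ``target_identity`` percent or below.

    Positions in ``frozen`` are never touched (used to preserve functional
    motifs in planted pheromone precursors).  Deterministic per seed.
    """
    if len(seq) < 50:
        raise ValueError("mutate_protein requires length >= 50")
    if not 20 <= target_identity <= 100:
        raise ValueError("target_identity must be in [20, 100]")
    if target_identity == 100:
        return seq
    rng = np.random.default_rng(seed)
    n = len(seq)
    mutable = [i for i in range(n) if i not in frozen]
    order = rng.permutation(len(mutable))
    out = list(seq)
    changed = 0
    for idx in order:
        if 100.0 * (n - changed) / n <= target_identity:
            break
        pos = mutable[idx]
        choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
        out[pos] = choices[rng.integers(len(choices))]
        changed += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# layout

@dataclass
class _GeneSpec:
    key: str
    label: str
    strand: str
    proteins: dict[str, str]          # allele label (or "*") -> protein
    allele_of: Optional[str] = None   # None | "A" | "B"
    intron: Optional[tuple[int, str]] = None   # (split offset in CDS nt, intron seq)
    only_architecture: Optional[str] = None    # "inserted" for matB2-only genes

    def protein_for(self, design: StrainDesign) -> str:
        if self.allele_of is None:
            return self.proteins["*"]
        allele = design.a_allele if self.allele_of == "A" else design.b_allele
        if allele not in self.proteins:
            raise ValueError(f"gene {self.key!r}: no protein for allele {allele!r}")
        return self.proteins[allele]


_SCALES = {
    # genes per chromosome, protein length range, spacer length range
    "test": dict(genes=(7, 11), plen=(100, 300), spacer=(2000, 4500)),
    "paper": dict(genes=(400, 560), plen=(100, 600), spacer=(1500, 3500)),
}


def _allele_variants(base: str, key: str, targets: dict[str, float], seed: int,
                     frozen: frozenset = frozenset()) -> dict[str, str]:
    """Allele 1 is the base protein; later alleles are mutated copies."""
    out = {}
    for allele, target in targets.items():
        if allele.endswith("1"):
            out[allele] = base
        else:
            out[allele] = mutate_protein(base, target, _derived_seed(seed, f"mut:{key}:{allele}"),
                                         frozen=frozen)
    return out


def _build_layout(seed: int, scale: str, n_chroms: int, gc: float,
                  designs: list[StrainDesign]):
    """The shared per-chromosome element lists and the marker protein table."""
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; options: {sorted(_SCALES)}")
    params = _SCALES[scale]
    rng = np.random.default_rng(_derived_seed(seed, "layout"))

    a_alleles = sorted({d.a_allele for d in designs})
    b_alleles = sorted({d.b_allele for d in designs})
    d0 = designs[0]

    # marker base proteins (allele "<locus>1") and mutated variants
    hd1 = _allele_variants("M" + "".join(rng.choice(list(AMINO_ACIDS), size=549)),
                           "HD1", {a: d0.hd1_identity for a in a_alleles}, seed)
    hd2 = _allele_variants("M" + "".join(rng.choice(list(AMINO_ACIDS), size=519)),
                           "HD2", {a: d0.hd2_identity for a in a_alleles}, seed)
    ste3_base = random_protein(rng, 450)
    ste3 = _allele_variants(ste3_base, "STE3",
                            {b: d0.ste3_identity for b in b_alleles}, seed)
    phb_base = "MAFSER" + "".join(rng.choice(list(AMINO_ACIDS), size=50)) + "CVIA"
    phb = _allele_variants(phb_base, "PhB", {b: d0.phb_identity for b in b_alleles},
                           seed, frozen=frozenset(range(6)) | frozenset(range(56, 60)))
    for allele, pep in phb.items():
        call = classify_pheromone_precursor(pep)
        if not call.verdict:
            raise AssertionError(f"planted PhB allele {allele} fails its own filter")

    # decoys: each fails exactly one pheromone-precursor rule
    decoy_caax_fail = "MAFSER" + "".join(rng.choice(list(AMINO_ACIDS), size=22)) + "CVIR"
    while True:
        interior = "".join(rng.choice(list(AMINO_ACIDS), size=22))
        decoy_nterm_fail = "MSSQGG" + interior + "CVIA"
        if "AF" not in decoy_nterm_fail and "ER" not in decoy_nterm_fail:
            break
    decoys = {"decoyCAAX": (decoy_caax_fail, "caax"),
              "decoyNTERM": (decoy_nterm_fail, "nterm")}

    def spacer(lo=None, hi=None):
        lo = lo or params["spacer"][0]
        hi = hi or params["spacer"][1]
        return ("seq", random_dna(rng, int(rng.integers(lo, hi)), gc))

    def background_gene(key):
        plen = int(rng.integers(*params["plen"]))
        pep = random_protein(rng, plen)
        strand = "+" if rng.random() < 0.5 else "-"
        intron = None
        if rng.random() < 0.3:
            split = 3 * int(rng.integers(10, plen - 10))
            intron = (split, random_dna(rng, int(rng.integers(60, 91)), gc))
        label = _NEUTRAL_LABELS[int(rng.integers(len(_NEUTRAL_LABELS)))]
        return ("gene", _GeneSpec(key, label, strand, {"*": pep}, intron=intron))

    def named_gene(key, label, strand="+", plen=200, intron=None):
        return ("gene", _GeneSpec(key, label, strand, {"*": random_protein(rng, plen)},
                                  intron=intron))

    layout: dict[str, list] = {}
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1:02d}"
        elements: list = [("tel5", None)]
        elements.append(spacer(1000, 2500))
        n_genes = int(rng.integers(*params["genes"]))
        half = n_genes // 2
        for gi in range(half):
            elements.append(background_gene(f"{chrom}_bg{gi:03d}"))
            elements.append(spacer())
        if ci == A_CHROM_INDEX:
            split = 3 * int(rng.integers(40, 140))
            elements += [
                named_gene("ODDT", "conserved hypothetical protein ODDT", "+", 310),
                spacer(),
                ("gene", _GeneSpec("HD1", "homeobox KN domain protein", "-",
                                   hd1, allele_of="A",
                                   intron=(split, random_dna(rng, 72, gc)))),
                spacer(1200, 2400),
                ("gene", _GeneSpec("HD2", "homeobox domain protein", "+",
                                   hd2, allele_of="A")),
                spacer(),
                named_gene("PRL22", "conserved hypothetical protein PRL22", "-", 260),
                spacer(),
            ]
        if ci == B_CHROM_INDEX:
            elements += [
                named_gene("STEA", "STE like transcription factor", "-", 330),
                spacer(),
                named_gene("APP1", "phosphatidate phosphatase", "+", 280),
                spacer(),
                named_gene("USP14", "ubiquitin carboxyl-terminal hydrolase", "+", 300),
                spacer(1500, 2500),
                # decoy ORF upstream of PhB; TAA guard pins its reading frame
                ("seq", random_dna(rng, 400, gc) + "TAA"),
                ("raw", "decoyCAAX", reverse_translate(decoys["decoyCAAX"][0],
                                                       _derived_seed(seed, "cds:decoyCAAX"))),
                ("seq", random_dna(rng, 700, gc) + "TAA"),
                ("gene", _GeneSpec("PhB", "pheromone precursor", "+", phb,
                                   allele_of="B")),
                ("insertion_start", None),
                spacer(700, 1100),
                named_gene("ZNF622", "cytoplasm protein", "-", 180),
                spacer(600, 900),
                named_gene("DBP10", "ATP-dependent RNA helicase", "-", 210),
                spacer(600, 900),
                named_gene("STE12", "STE like transcription factor STE12", "+", 230),
                ("insertion_end", None),
                spacer(800, 1200),
                ("gene", _GeneSpec("STE3", "pheromone receptor", "+", ste3,
                                   allele_of="B")),
                ("seq", random_dna(rng, 500, gc) + "TAA"),
                ("raw", "decoyNTERM", reverse_translate(decoys["decoyNTERM"][0],
                                                        _derived_seed(seed, "cds:decoyNTERM"))),
                spacer(1500, 2500),
                named_gene("CLA4", "serine/threonine-protein kinase", "+", 350),
                spacer(),
                named_gene("MUN", "homoaconitate hydratase", "-", 320),
                spacer(),
            ]
        for gi in range(half, n_genes):
            elements.append(background_gene(f"{chrom}_bg{gi:03d}"))
            elements.append(spacer())
        elements.append(("tel3", None))
        layout[chrom] = elements

    markers = {"HD1": hd1, "HD2": hd2, "PhB": phb, "STE3": ste3}
    insertion_keys = ["ZNF622", "DBP10", "STE12"]
    return layout, markers, decoys, insertion_keys


def _realize_gene(spec: _GeneSpec, design: StrainDesign, seed: int) -> tuple[str, list[tuple[int, int]], str]:
    """(genomic nt, local CDS segments, protein) for one gene in one strain."""
    pep = spec.protein_for(design)
    allele = ("" if spec.allele_of is None
              else (design.a_allele if spec.allele_of == "A" else design.b_allele))
    cds = reverse_translate(pep, _derived_seed(seed, f"cds:{spec.key}:{allele}"))
    if spec.intron is None:
        pieces, segs_tx = [cds], [(0, len(cds))]
    else:
        split, intron = spec.intron
        pieces = [cds[:split], intron, cds[split:]]
        segs_tx = [(0, split), (split + len(intron), split + len(intron) + len(cds) - split)]
    tx = "".join(pieces)
    if spec.strand == "+":
        return tx, segs_tx, pep
    g = revcomp(tx)
    L = len(tx)
    segs = sorted((L - e, L - s) for s, e in segs_tx)
    return g, segs, pep


def generate_strain_set(designs: list[StrainDesign] | None = None,
                        scale: str = "test", seed: int = 0,
                        n_chroms: int = DEFAULT_N_CHROMS,
                        telomere_copies: int = DEFAULT_TELOMERE_COPIES,
                        gc: float = DEFAULT_GC,
                        outdir: str | Path | None = None
                        ) -> tuple[dict[str, StrainData], TruthManifest]:
    """Generate a synthetic strain set and its ground-truth manifest.

    With ``outdir`` set, writes per-strain ``<name>.fa`` / ``<name>.gff3``
    / ``<name>.faa`` plus ``truth.json``.  Identical arguments produce
    byte-identical outputs.
    """
    designs = designs if designs is not None else default_design()
    names = [d.strain_name for d in designs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain names in design list")

    layout, markers, decoys, insertion_keys = _build_layout(seed, scale, n_chroms,
                                                            gc, designs)
    tel5 = DEFAULT_MONOMER_5 * telomere_copies
    tel3 = DEFAULT_MONOMER_3 * telomere_copies

    manifest = TruthManifest(seed=seed, scale=scale)
    manifest.marker_identity_targets = {
        "HD1": designs[0].hd1_identity, "HD2": designs[0].hd2_identity,
        "PhB": designs[0].phb_identity, "STE3": designs[0].ste3_identity,
    }
    strains: dict[str, StrainData] = {}

    for design in designs:
        genome = SequenceSet()
        annots = AnnotationSet()
        truth = dict(a_allele=design.a_allele, b_allele=design.b_allele,
                     b_architecture=design.b_architecture,
                     chrom_lengths={}, telomeres=[], decoys=[],
                     a_locus=None, b_locus=None)
        gene_coords: dict[str, tuple[str, int, int]] = {}
        for chrom, elements in layout.items():
            parts: list[str] = []
            pos = 0
            pending_genes: list[GeneModel] = []
            in_insertion = False
            for el in elements:
                kind = el[0]
                if kind == "insertion_start":
                    in_insertion = True
                    continue
                if kind == "insertion_end":
                    in_insertion = False
                    continue
                if in_insertion and design.b_architecture != "inserted":
                    continue
                if kind == "tel5":
                    parts.append(tel5)
                    pos += len(tel5)
                elif kind == "tel3":
                    parts.append(tel3)
                    pos += len(tel3)
                elif kind == "seq":
                    parts.append(el[1])
                    pos += len(el[1])
                elif kind == "raw":
                    _, key, nt = el
                    truth["decoys"].append(dict(key=key, chrom=chrom,
                                                span=[pos, pos + len(nt)],
                                                peptide=decoys[key][0],
                                                fails=decoys[key][1]))
                    parts.append(nt)
                    pos += len(nt)
                elif kind == "gene":
                    spec = el[1]
                    g_nt, segs, pep = _realize_gene(spec, design, seed)
                    gene = GeneModel(gene_id=f"{design.strain_name}_{spec.key}",
                                     chrom=chrom, start=pos, end=pos + len(g_nt),
                                     strand=spec.strand,
                                     cds_segments=[(pos + s, pos + e) for s, e in segs],
                                     labels=[spec.label])
                    pending_genes.append(gene)
                    gene_coords[spec.key] = (chrom, pos, pos + len(g_nt))
                    parts.append(g_nt)
                    pos += len(g_nt)
                else:
                    raise AssertionError(f"unknown layout element {kind!r}")
            seq = "".join(parts)
            genome.add(SequenceRecord(chrom, seq))
            annots.chrom_lengths[chrom] = len(seq)
            truth["chrom_lengths"][chrom] = len(seq)
            truth["telomeres"] += [
                dict(chrom=chrom, end="five_prime", span=[0, len(tel5)],
                     copies=telomere_copies),
                dict(chrom=chrom, end="three_prime",
                     span=[len(seq) - len(tel3), len(seq)], copies=telomere_copies),
            ]
            for gene in pending_genes:
                annots.add(gene)

        sid = design.strain_name
        a_chrom, a_lo, _ = gene_coords["HD1"]
        _, _, a_hi = gene_coords["HD2"]
        truth["a_locus"] = dict(chrom=a_chrom, span=[a_lo, a_hi],
                                hd1=f"{sid}_HD1", hd2=f"{sid}_HD2")
        b_chrom, phb_lo, phb_hi = gene_coords["PhB"]
        _, ste3_lo, ste3_hi = gene_coords["STE3"]
        inserted = ([f"{sid}_{k}" for k in insertion_keys]
                    if design.b_architecture == "inserted" else [])
        truth["b_locus"] = dict(chrom=b_chrom,
                                span=[min(phb_lo, ste3_lo), max(phb_hi, ste3_hi)],
                                phb=f"{sid}_PhB", ste3=f"{sid}_STE3",
                                insertion_genes=inserted)

        proteins = SequenceSet()
        for gene in annots:
            proteins.add(extract_protein(genome, gene))
        strains[sid] = StrainData(sid, genome, annots, proteins)
        manifest.strains[sid] = truth

    from itertools import combinations
    for d1, d2 in combinations(designs, 2):
        if d1.a_allele != d2.a_allele and d1.b_allele != d2.b_allele:
            manifest.expected_compatible_pairs.append((d1.strain_name, d2.strain_name))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, data in strains.items():
            write_fasta(data.genome, outdir / f"{sid}.fa")
            write_gff3(data.annots, outdir / f"{sid}.gff3")
            write_fasta(data.proteins, outdir / f"{sid}.faa")
        manifest.to_json(outdir / "truth.json")
    return strains, manifest


def validate_manifest(strains: dict[str, StrainData], manifest: TruthManifest) -> list[str]:
    """Cross-check emitted files against the truth manifest.

    Returns a list of inconsistency messages (empty when everything the
    manifest claims is present in the sequences and annotations).
    """
    problems: list[str] = []
    for sid, truth in manifest.strains.items():
        data = strains[sid]
        for chrom, length in truth["chrom_lengths"].items():
            if len(data.genome[chrom]) != length:
                problems.append(f"{sid}/{chrom}: length mismatch")
        for tel in truth["telomeres"]:
            s, e = tel["span"]
            seq = data.genome[tel["chrom"]].seq[s:e]
            monomer = DEFAULT_MONOMER_5 if tel["end"] == "five_prime" else DEFAULT_MONOMER_3
            if seq != monomer * tel["copies"]:
                problems.append(f"{sid}/{tel['chrom']}: telomere span content mismatch")
        for gid in (truth["a_locus"]["hd1"], truth["a_locus"]["hd2"],
                    truth["b_locus"]["phb"], truth["b_locus"]["ste3"],
                    *truth["b_locus"]["insertion_genes"]):
            if gid not in data.annots:
                problems.append(f"{sid}: truth gene {gid} missing from annotation")
        for gene in data.annots:
            rec = extract_protein(data.genome, gene)
            if "internal_stop" in rec.flags:
                problems.append(f"{sid}/{gene.gene_id}: internal stop codon")
        phb_pep = data.proteins[truth["b_locus"]["phb"]].seq
        if not classify_pheromone_precursor(phb_pep).verdict:
            problems.append(f"{sid}: planted PhB fails the precursor filter")
        for decoy in truth["decoys"]:
            call = classify_pheromone_precursor(decoy["peptide"])
            expect = dict(caax=(False, True), nterm=(True, False))[decoy["fails"]]
            if (call.caax_ok, call.nterm_ok) != expect:
                problems.append(f"{sid}/{decoy['key']}: wrong rule outcome "
                                f"(caax={call.caax_ok}, nterm={call.nterm_ok})")
    return problems
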