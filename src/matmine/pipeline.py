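"""End-to-end orchestration: io -> telomeres -> loci -> alleles -> genotypes
-> compatibility -> locus synteny, with per-strain failure isolation.

Each strain is analysed independently; a failing strain is recorded and
skipped by the cross-strain stages rather than aborting the run.  Reports
are plain dataclasses with ``to_dict`` serialisers so the CLI can emit
JSON/TSV twins; re-running with identical inputs and configuration gives
identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from matmine import alleles as al
from matmine import compat as cp
from matmine import hdlocus as hd
from matmine import prlocus as pr
from matmine import synteny as sy
from matmine import telomeres as tel
from matmine.genomeio import (
    AnnotationSet,
    AssemblyStats,
    SequenceSet,
    assembly_stats,
    extract_protein,
    read_fasta,
    read_gff3,
)
from matmine.simulate import StrainData

log = logging.getLogger("matmine")


@dataclass
class RunConfig:
    """All stage parameters with their documented defaults."""

    # telomeres
    monomer5: str = tel.DEFAULT_MONOMER_5
    monomer3: str = tel.DEFAULT_MONOMER_3
    min_copies: int = tel.DEFAULT_MIN_COPIES
    max_offset: int = tel.DEFAULT_MAX_OFFSET
    # A locus
    hd_keywords: tuple = hd.DEFAULT_HD_KEYWORDS
    max_gap: int = hd.DEFAULT_MAX_GAP
    a_flank: int = hd.DEFAULT_A_FLANK
    # B locus
    receptor_keywords: tuple = pr.DEFAULT_RECEPTOR_KEYWORDS
    precursor_keywords: tuple = pr.DEFAULT_PRECURSOR_KEYWORDS
    scan_flank: int = pr.DEFAULT_FLANK
    min_orf_nt: int = pr.DEFAULT_MIN_ORF_NT
    sig_window: int = pr.DEFAULT_SIG_WINDOW
    b_flank: int = pr.DEFAULT_B_FLANK
    # alignment / typing
    matrix: str = al.DEFAULT_MATRIX
    gap_open: float = al.DEFAULT_GAP_OPEN
    gap_extend: float = al.DEFAULT_GAP_EXTEND
    # synteny / strain-specific genes
    match_threshold: float = sy.DEFAULT_MATCH_THRESHOLD
    hit_identity: float = sy.DEFAULT_HIT_IDENTITY
    hit_coverage: float = sy.DEFAULT_HIT_COVERAGE
    run_synteny: bool = True
    run_strain_specific: bool = True
    bipolar: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["hd_keywords"] = list(self.hd_keywords)
        data["receptor_keywords"] = list(self.receptor_keywords)
        data["precursor_keywords"] = list(self.precursor_keywords)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("hd_keywords", "receptor_keywords", "precursor_keywords"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class StrainReport:
    """Consolidated per-strain findings."""

    strain: str
    stats: Optional[AssemblyStats] = None
    telomeres: Optional[tel.TelomereReport] = None
    hd_pair: Optional[hd.HDPair] = None
    a_locus: Optional[hd.LocusRegion] = None
    b_locus: Optional[hd.LocusRegion] = None
    pheromone_calls: list = field(default_factory=list)
    b_insertion_genes: list = field(default_factory=list)
    marker_proteins: dict = field(default_factory=dict)   # HD1/HD2/PhB/STE3 -> aa
    genotype: Optional[al.MatingGenotype] = None
    warnings: list = field(default_factory=list)
    error: Optional[str] = None

    def to_dict(self) -> dict:
        def locus(reg):
            if reg is None:
                return None
            return dict(locus_type=reg.locus_type, chrom=reg.chrom,
                        span=list(reg.span), anchors=list(reg.anchor_ids),
                        members=[g.gene_id for g in reg.member_genes],
                        warnings=list(reg.warnings))
        return dict(
            strain=self.strain,
            stats=dataclasses.asdict(self.stats) if self.stats else None,
            telomeres=dict(total=self.telomeres.total_telomeres,
                           t2t=self.telomeres.t2t_chromosomes,
                           arrays=self.telomeres.to_rows()) if self.telomeres else None,
            a_locus=locus(self.a_locus),
            b_locus=locus(self.b_locus),
            b_insertion_genes=[g.gene_id for g in self.b_insertion_genes],
            n_pheromone_calls=len(self.pheromone_calls),
            n_verdict_true=sum(1 for c in self.pheromone_calls if c.verdict),
            genotype=self.genotype.composite if self.genotype else None,
            warnings=list(self.warnings),
            error=self.error,
        )


@dataclass
class PipelineResult:
    """Per-strain reports plus the cross-strain tables."""

    strain_reports: dict[str, StrainReport]
    allele_a: Optional[al.AlleleAssignment] = None
    allele_b: Optional[al.AlleleAssignment] = None
    genotypes: list = field(default_factory=list)
    compatibility: Optional[cp.CompatibilityMatrix] = None
    marker_identities: dict = field(default_factory=dict)  # marker -> {pair: pct}
    synteny: dict = field(default_factory=dict)            # (s1,s2,locus) -> ArchitectureCall
    strain_specific: dict = field(default_factory=dict)    # (s1,s2) -> (set, set)

    @property
    def failed_strains(self) -> list[str]:
        return [s for s, r in self.strain_reports.items() if r.error]


def analyze_strain(name: str, genome: SequenceSet, annots: AnnotationSet,
                   config: RunConfig) -> StrainReport:
    """Run all single-strain stages for one genome + annotation."""
    report = StrainReport(strain=name)
    report.stats = assembly_stats(genome)
    log.info("%s: %d contigs, N50 %d bp, GC %.2f%%", name, report.stats.n_contigs,
             report.stats.n50, report.stats.gc_percent)

    report.telomeres = tel.scan_genome(genome, config.monomer5, config.monomer3,
                                       config.min_copies, config.max_offset)
    log.info("%s: %d telomeres, %d telomere-to-telomere chromosomes", name,
             report.telomeres.total_telomeres, report.telomeres.t2t_chromosomes)

    # A locus
    pairs = hd.find_hd_pairs(annots, config.hd_keywords, config.max_gap)
    if pairs:
        if len(pairs) > 1:
            report.warnings.append(f"{len(pairs)} candidate HD pairs; using smallest gap")
        report.hd_pair = pairs[0]
        report.a_locus = hd.define_locus(report.hd_pair, annots,
                                         flank=config.a_flank, locus_type="A")
        report.marker_proteins["HD1"] = extract_protein(genome, report.hd_pair.hd1).seq
        report.marker_proteins["HD2"] = extract_protein(genome, report.hd_pair.hd2).seq
        log.info("%s: A locus on %s span %s", name, report.a_locus.chrom,
                 report.a_locus.span)
    else:
        report.warnings.append("no divergent HD pair found")

    # B locus
    receptors = pr.find_receptors(annots, config.receptor_keywords)
    if receptors:
        if len(receptors) > 1:
            report.warnings.append(f"{len(receptors)} receptor genes; using first")
        receptor = receptors[0]
        report.pheromone_calls = pr.scan_receptor_flanks(
            receptor, genome, config.scan_flank, config.min_orf_nt, config.sig_window)
        region, insertion = pr.define_b_locus(receptor, report.pheromone_calls,
                                              annots, flank=config.b_flank,
                                              precursor_keywords=config.precursor_keywords)
        report.b_locus = region
        report.b_insertion_genes = insertion
        report.warnings.extend(region.warnings)
        report.marker_proteins["STE3"] = extract_protein(genome, receptor).seq
        if len(region.anchor_ids) > 1:
            anchor2 = region.anchor_ids[1]
            if anchor2 in annots:
                report.marker_proteins["PhB"] = extract_protein(genome, annots[anchor2]).seq
            else:
                best = [c for c in report.pheromone_calls if c.verdict]
                if best:
                    report.marker_proteins["PhB"] = best[0].orf.peptide
        log.info("%s: B locus on %s span %s, %d inter-anchor genes", name,
                 region.chrom, region.span, len(insertion))
    else:
        report.warnings.append("no pheromone receptor gene found")
    return report


def _marker_identity_table(reports: dict[str, StrainReport],
                           assignment: al.AlleleAssignment,
                           markers: tuple[str, ...]) -> dict:
    """Representative inter-allele identity per marker (class representatives)."""
    table: dict[str, dict[str, float]] = {}
    reps = {lab: strains[0] for lab, strains in assignment.classes.items()}
    labs = sorted(reps)
    for marker in markers:
        table[marker] = {}
        for i, l1 in enumerate(labs):
            for l2 in labs[i + 1:]:
                p1 = reports[reps[l1]].marker_proteins.get(marker)
                p2 = reports[reps[l2]].marker_proteins.get(marker)
                if p1 and p2:
                    res = al.global_identity(p1, p2, l1, l2)
                    table[marker][f"{l1}-{l2}"] = res.identity_percent
    return table


def run_pipeline(strain_inputs: dict, config: RunConfig | None = None) -> PipelineResult:
    """Run every stage over a set of strains.

    ``strain_inputs`` maps strain name to either a :class:`StrainData` or a
    ``(fasta_path, gff3_path)`` pair.  Single-strain stages run per strain
    with failures isolated; cross-strain stages (allele typing, genotypes,
    compatibility, synteny, strain-specific genes) use the strains whose
    loci resolved.
    """
    config = config or RunConfig()
    reports: dict[str, StrainReport] = {}
    data: dict[str, StrainData] = {}
    for name, inp in strain_inputs.items():
        try:
            if isinstance(inp, StrainData):
                sd = inp
            else:
                fasta, gff3 = inp
                annots = read_gff3(gff3)
                genome = read_fasta(fasta)
                proteins = SequenceSet()
                for gene in annots:
                    proteins.add(extract_protein(genome, gene))
                sd = StrainData(name, genome, annots, proteins)
            data[name] = sd
            reports[name] = analyze_strain(name, sd.genome, sd.annots, config)
        except Exception as exc:   # noqa: BLE001 - stage isolation is the contract
            log.error("strain %s failed: %s", name, exc)
            reports[name] = StrainReport(strain=name, error=str(exc))

    result = PipelineResult(strain_reports=reports)
    typed = {s: r for s, r in reports.items()
             if not r.error and {"HD1", "HD2", "PhB", "STE3"} <= set(r.marker_proteins)}
    if len(typed) >= 1:
        a_markers = {s: r.marker_proteins["HD1"] + r.marker_proteins["HD2"]
                     for s, r in typed.items()}
        b_markers = {s: r.marker_proteins["PhB"] + r.marker_proteins["STE3"]
                     for s, r in typed.items()}
        result.allele_a = al.assign_alleles(a_markers, locus="A")
        result.allele_b = al.assign_alleles(b_markers, locus="B")
        result.genotypes = al.genotype_strains(result.allele_a, result.allele_b)
        for g in result.genotypes:
            reports[g.strain].genotype = g
        result.marker_identities = {
            **_marker_identity_table(typed, result.allele_a, ("HD1", "HD2")),
            **_marker_identity_table(typed, result.allele_b, ("PhB", "STE3")),
        }
    if len(result.genotypes) >= 2:
        result.compatibility = cp.compatibility_matrix(result.genotypes,
                                                       bipolar=config.bipolar)
        log.info("compatibility: %d of %d pairs", result.compatibility.n_compatible,
                 len(result.compatibility.matrix))
    elif result.genotypes:
        log.warning("single typed strain; compatibility stage skipped")

    strains_ok = sorted(typed)
    if config.run_synteny:
        for i, s1 in enumerate(strains_ok):
            for s2 in strains_ok[i + 1:]:
                for locus_name, attr in (("A", "a_locus"), ("B", "b_locus")):
                    la, lb = getattr(reports[s1], attr), getattr(reports[s2], attr)
                    if la is None or lb is None:
                        continue
                    pa = {g.gene_id: data[s1].proteins[g.gene_id].seq
                          for g in la.member_genes}
                    pb = {g.gene_id: data[s2].proteins[g.gene_id].seq
                          for g in lb.member_genes}
                    pairings = sy.match_locus_genes(la, pa, lb, pb,
                                                    config.match_threshold)
                    result.synteny[(s1, s2, locus_name)] = sy.call_architecture(
                        pairings, la, lb)
    if config.run_strain_specific:
        for i, s1 in enumerate(strains_ok):
            for s2 in strains_ok[i + 1:]:
                pa = {r.id: r.seq for r in data[s1].proteins}
                pb = {r.id: r.seq for r in data[s2].proteins}
                result.strain_specific[(s1, s2)] = sy.find_strain_specific_genes(
                    pa, pb, config.hit_identity, config.hit_coverage)
    return result
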