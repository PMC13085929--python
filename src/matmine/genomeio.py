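"""Genome/annotation I/O, the shared data model, CDS translation and assembly stats.

Internal coordinates are 0-based half-open throughout; external files keep
their native conventions (GFF3 is 1-based inclusive).  Nucleotide sequences
are uppercase over ``ACGTN``; protein sequences over the 20 standard amino
acids plus ``X`` (unknown) and ``*`` (stop).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_RE = re.compile(r"^[ACGTN]+$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file; message names the offending line where known."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence, nucleotide or protein.

    Attributes
    ----------
    id : str
        Record identifier, unique within a :class:`SequenceSet`.
    seq : str
        Uppercase sequence; alphabet must match ``moltype``.
    moltype : str
        ``"nucleotide"`` or ``"protein"``.
    flags : tuple of str
        Non-fatal quality warnings (e.g. internal stop codons).
    """

    id: str
    seq: str
    moltype: str = NUCLEOTIDE
    flags: tuple = ()

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        pattern = _NT_RE if self.moltype == NUCLEOTIDE else _AA_RE
        if self.moltype not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        if not pattern.match(self.seq):
            bad = sorted(set(self.seq) - set(pattern.pattern[2:-3]))
            raise ValueError(
                f"record {self.id!r}: illegal {self.moltype} characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()):
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self._records[rec.id] = rec

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._records[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return list(self) == list(other)


@dataclass
class GeneModel:
    """A gene with its CDS structure and free-text functional labels.

    Coordinates are 0-based half-open on the chromosome.  ``cds_segments``
    are sorted by genomic coordinate regardless of strand; transcription
    order for minus-strand genes is the reverse.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        self.cds_segments = sorted(tuple(s) for s in self.cds_segments)
        prev_end = None
        for s, e in self.cds_segments:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id!r}: CDS segment [{s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: overlapping CDS segments")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def matches_keywords(self, keywords: Iterable[str]) -> bool:
        """Case-insensitive substring match of any keyword against any label."""
        lowered = [lab.lower() for lab in self.labels]
        return any(kw.lower() in lab for kw in keywords for lab in lowered)


class AnnotationSet:
    """Gene models grouped by chromosome, with optional chromosome lengths."""

    def __init__(self, genes: Iterable[GeneModel] = (), chrom_lengths: dict[str, int] | None = None):
        self._genes: dict[str, GeneModel] = {}
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        """Genes on one chromosome in coordinate order."""
        return sorted((g for g in self._genes.values() if g.chrom == chrom),
                      key=lambda g: (g.start, g.end, g.gene_id))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose interval intersects [start, end), in coordinate order."""
        return [g for g in self.on_chrom(chrom) if g.start < end and g.end > start]


@dataclass(frozen=True)
class AssemblyStats:
    """Contig-level summary statistics of an assembly."""

    n_contigs: int
    total_length: int
    max_length: int
    n50: int
    gc_percent: float


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, moltype: str = NUCLEOTIDE) -> SequenceSet:
    """Read a (multi-)FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased; record order is preserved.  An empty file
    yields an empty set.  Illegal characters raise :class:`ParseError`
    naming the line number.
    """
    path = Path(path)
    records = SequenceSet()
    pattern = _NT_RE if moltype == NUCLEOTIDE else _AA_RE
    with open(path) as fh:
        cur_id, cur_chunks, cur_line = None, [], 0
        def _flush():
            if cur_id is None:
                return
            seq = "".join(cur_chunks)
            try:
                records.add(SequenceRecord(cur_id, seq, moltype))
            except ValueError as exc:
                raise ParseError(f"{path}:{cur_line}: {exc}") from exc
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                cur_id, cur_chunks, cur_line = header[0], [], lineno
            else:
                if cur_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                up = line.upper()
                if not pattern.match(up):
                    raise ParseError(f"{path}:{lineno}: illegal characters in sequence")
                cur_chunks.append(up)
        _flush()
    return records


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> AnnotationSet:
    """Read gene/mRNA/CDS features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open.  CDS features are grouped per gene by following Parent
    attributes through mRNAs.  Functional labels are taken from ``product``
    and ``Note`` attributes on the gene or its transcripts.  A CDS whose
    Parent chain does not reach a gene raises :class:`ParseError`.
    """
    path = Path(path)
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break

    parent_of = {}
    for feat in db.all_features():
        for par in feat.attributes.get("Parent", []):
            parent_of.setdefault(feat.id, par)

    def _gene_of(feature_id: str) -> str | None:
        seen = set()
        cur = feature_id
        while cur is not None and cur not in seen:
            seen.add(cur)
            try:
                if db[cur].featuretype == "gene":
                    return cur
            except gffutils.FeatureNotFoundError:
                return None
            cur = parent_of.get(cur)
        return None

    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        labels = list(g.attributes.get("product", [])) + list(g.attributes.get("Note", []))
        genes[g.id] = dict(chrom=g.seqid, start=g.start - 1, end=g.end,
                           strand=g.strand, cds=[], labels=labels)
    for mrna in db.features_of_type("mRNA"):
        gid = _gene_of(mrna.id)
        if gid is not None:
            for key in ("product", "Note"):
                for lab in mrna.attributes.get(key, []):
                    if lab not in genes[gid]["labels"]:
                        genes[gid]["labels"].append(lab)
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        gid = None
        for par in parents:
            gid = _gene_of(par)
            if gid is not None:
                break
        if gid is None:
            raise ParseError(
                f"{path}: CDS feature at {cds.seqid}:{cds.start}-{cds.end} "
                f"(Parent={','.join(parents) or 'none'}) has no resolvable parent gene")
        genes[gid]["cds"].append((cds.start - 1, cds.end))

    out = AnnotationSet(chrom_lengths=chrom_lengths)
    for gid, info in genes.items():
        out.add(GeneModel(gene_id=gid, chrom=info["chrom"], start=info["start"],
                          end=info["end"], strand=info["strand"],
                          cds_segments=info["cds"], labels=info["labels"]))
    return out


def write_gff3(annots: AnnotationSet, path: str | Path, source: str = "matmine") -> None:
    """Write an :class:`AnnotationSet` as GFF3 (gene/mRNA/CDS, ID/Parent linked)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annots.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in sorted(annots, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={gene.gene_id}"
            if gene.labels:
                attrs += ";product=" + ",".join(gene.labels)
            fh.write("\t".join([gene.chrom, source, "gene", str(gene.start + 1),
                                str(gene.end), ".", gene.strand, ".", attrs]) + "\n")
            tid = f"{gene.gene_id}.t1"
            fh.write("\t".join([gene.chrom, source, "mRNA", str(gene.start + 1),
                                str(gene.end), ".", gene.strand, ".",
                                f"ID={tid};Parent={gene.gene_id}"]) + "\n")
            segs = gene.cds_segments
            order = segs if gene.strand == "+" else segs[::-1]
            phase, cum = 0, 0
            phases = {}
            for s, e in order:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for i, (s, e) in enumerate(segs):
                fh.write("\t".join([gene.chrom, source, "CDS", str(s + 1), str(e),
                                    ".", gene.strand, str(phases[(s, e)]),
                                    f"ID={gene.gene_id}.cds{i};Parent={tid}"]) + "\n")


# ---------------------------------------------------------------------------
# Translation

def extract_protein(genome: SequenceSet, gene: GeneModel, codon_table: int = 1) -> SequenceRecord:
    """Assemble a gene's CDS from the genome and translate it.

    Segments are concatenated in genomic order and reverse-complemented for
    minus-strand genes (transcription order).  The trailing stop codon is
    stripped.  An internal stop codon sets the ``internal_stop`` flag on the
    returned record rather than raising.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom].seq
    if not gene.cds_segments:
        raise ValueError(f"gene {gene.gene_id!r} has no CDS segments")
    if gene.cds_segments[-1][1] > len(chrom_seq):
        raise ValueError(f"gene {gene.gene_id!r}: CDS outside chromosome bounds")
    cds = "".join(chrom_seq[s:e] for s, e in gene.cds_segments)
    if gene.strand == "-":
        cds = revcomp(cds)
    if len(cds) % 3:
        raise ValueError(f"gene {gene.gene_id!r}: CDS length {len(cds)} not divisible by 3")
    pep = str(Seq(cds).translate(table=codon_table))
    if pep.endswith("*"):
        pep = pep[:-1]
    if not pep:
        raise ValueError(f"gene {gene.gene_id!r}: empty translation")
    flags = ("internal_stop",) if "*" in pep else ()
    return SequenceRecord(gene.gene_id, pep, PROTEIN, flags=flags)


# ---------------------------------------------------------------------------
# Assembly statistics

def assembly_stats(seqs: SequenceSet) -> AssemblyStats:
    """N50, total/max length and GC% of a nucleotide sequence set.

    N50 is the smallest contig length L such that contigs of length >= L
    cover at least half the total assembly.  GC% is computed over A/C/G/T
    positions only; N is excluded from the denominator.
    """
    records = list(seqs)
    if not records:
        raise ValueError("assembly_stats requires at least one record")
    if any(r.moltype != NUCLEOTIDE for r in records):
        raise TypeError("assembly_stats requires nucleotide records")
    lengths = sorted((len(r) for r in records), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum, n50 = 0, lengths[-1]
    for L in lengths:
        cum += L
        if cum >= half:
            n50 = L
            break
    gc = sum(r.seq.count("G") + r.seq.count("C") for r in records)
    acgt = sum(len(r) - r.seq.count("N") for r in records)
    gc_percent = 100.0 * gc / acgt if acgt else 0.0
    return AssemblyStats(n_contigs=len(records), total_length=total,
                         max_length=lengths[0], n50=n50, gc_percent=gc_percent)
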