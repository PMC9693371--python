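"""Sequence and annotation I/O: FASTA, GFF3, and the gene-model containers.

All coordinates are GFF3-style 1-based inclusive. Any half-open arithmetic
is local to a function and converted back before values leave it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "GenomeAnnotation",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "count_exons_introns",
    "reverse_complement",
    "spliced_cds",
    "translate_cds",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (nucleotide or amino acid)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def _check_intervals(name: str, intervals: list[tuple[int, int]]) -> None:
    prev_end = 0
    for s, e in intervals:
        if s > e:
            raise ValueError(f"{name}: interval end {e} < start {s}")
        if s <= prev_end:
            raise ValueError(f"{name}: intervals overlap or are unsorted")
        prev_end = e


@dataclass
class GeneModel:
    """One gene (representative transcript) on a chromosome.

    ``exons`` and ``cds`` are sorted, non-overlapping 1-based inclusive
    intervals in genomic order regardless of strand.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        _check_intervals(f"gene {self.id} exons", self.exons)
        _check_intervals(f"gene {self.id} CDS", self.cds)
        if not self.gene_id:
            self.gene_id = self.id

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GenomeAnnotation:
    """Chromosome table plus gene models, in deterministic order."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.chromosome not in lengths:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chromosome}")
            if g.end > lengths[g.chromosome]:
                raise ValueError(f"gene {g.id} extends past end of {g.chromosome}")

    @property
    def chromosome_order(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.chromosomes)}

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.id: g for g in self.genes}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order.

    Duplicate ids and empty files are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike, keep_isoforms: bool = True) -> GenomeAnnotation:
    """Parse a GFF3 file with gene/mRNA/exon/CDS features.

    With ``keep_isoforms`` each mRNA becomes a GeneModel named by its
    transcript id (the convention family tables use, where isoform
    suffixes like ``.1``/``.2`` are separate entries); otherwise the
    longest-CDS isoform represents the gene under the gene id.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])

    # orphan CDS/exon check: every CDS must reach a gene through its parents
    for feat in db.features_of_type("CDS"):
        ancestors = list(db.parents(feat, featuretype="gene"))
        if not ancestors:
            raise ValueError(f"CDS at {feat.seqid}:{feat.start}-{feat.end} has no parent gene")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.start > gene.end:
            raise ValueError(f"gene {gene.id}: end < start in GFF3")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            # gene with directly attached exons/CDS
            mrnas = [gene]
        models = []
        for m in mrnas:
            exons = [(c.start, c.end) for c in db.children(m, featuretype="exon", order_by="start")]
            cds = [(c.start, c.end) for c in db.children(m, featuretype="CDS", order_by="start")]
            for s, e in exons + cds:
                if s > e:
                    raise ValueError(f"feature under {m.id}: end {e} < start {s}")
            models.append(
                GeneModel(
                    id=m.id,
                    chromosome=gene.seqid,
                    start=m.start,
                    end=m.end,
                    strand=gene.strand,
                    exons=exons,
                    cds=cds,
                    gene_id=gene.id,
                )
            )
        if keep_isoforms:
            genes.extend(models)
        else:
            best = max(models, key=lambda g: (g.cds_length, g.id))
            best.id = gene.id
            genes.append(best)

    if not chrom_lengths:
        for g in genes:
            chrom_lengths[g.chromosome] = max(chrom_lengths.get(g.chromosome, 0), g.end)
    chromosomes = sorted(chrom_lengths.items())
    genes.sort(key=lambda g: (g.chromosome, g.start, g.id))
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike, source: str = "familyscan") -> None:
    """Write a GenomeAnnotation as spec-conformant GFF3 (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chromosome, g.start, g.id)):
            cols = [g.chromosome, source, "gene", str(g.start), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(cols + [f"ID={g.gene_id}"]) + "\n")
            fh.write(
                "\t".join(
                    [g.chromosome, source, "mRNA", str(g.start), str(g.end), ".", g.strand, ".",
                     f"ID={g.id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join([g.chromosome, source, "exon", str(s), str(e), ".", g.strand, ".",
                               f"Parent={g.id}"])
                    + "\n"
                )
            phase = 0
            cds_iter = g.cds if g.strand == "+" else list(reversed(g.cds))
            phased = {}
            for s, e in cds_iter:
                phased[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for s, e in g.cds:
                fh.write(
                    "\t".join([g.chromosome, source, "CDS", str(s), str(e), ".", g.strand,
                               str(phased[(s, e)]), f"Parent={g.id}"])
                    + "\n"
                )


def count_exons_introns(gene: GeneModel) -> tuple[int, int]:
    """Exon and intron counts; introns = exons - 1."""
    n = len(gene.exons)
    if n < 1:
        raise ValueError(f"gene {gene.id} has no exons")
    return n, n - 1


# ---------------------------------------------------------------------------
# sequence helpers

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def spliced_cds(gene: GeneModel, chromosome_seq: str) -> str:
    """Concatenate CDS intervals (strand-aware) into the coding sequence."""
    if not gene.cds:
        raise ValueError(f"gene {gene.id} has no CDS")
    parts = [chromosome_seq[s - 1 : e] for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_cds(cds: str) -> str:
    """Translate, dropping one trailing stop if present."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot
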