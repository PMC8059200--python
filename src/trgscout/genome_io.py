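"""Genome + annotation data model, FASTA/GFF3 I/O and elementary sequence operations.

All coordinates are internally 0-based, half-open. GFF3 uses 1-based inclusive
coordinates; the conversion happens only at the I/O boundary, in
:func:`read_genome` and :func:`write_genome`.

Only one transcript per gene is modelled. When an annotation carries several
mRNAs for a gene, the transcript with the longest total CDS is kept and the
choice is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")

Biotype = Literal["protein_coding", "pseudogene", "ncRNA"]


class GenomeValidationError(ValueError):
    """Raised when an annotation violates the structural data-model invariants."""


class GffParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the offending line."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a sequence region."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise GenomeValidationError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class GeneModel:
    """A single-transcript gene: ordered exons, CDS segments and derived introns.

    Exons and CDS segments are stored in genomic (ascending) coordinate order
    regardless of strand; translation order for minus-strand genes is handled
    at sequence-extraction time.
    """

    gene_id: str
    seq_region: str
    strand: str  # "+" or "-"
    exons: list[Interval]
    cds_segments: list[Interval] = field(default_factory=list)
    biotype: Biotype = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds_segments = sorted(self.cds_segments, key=lambda iv: iv.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise GenomeValidationError(f"{self.gene_id}: overlapping exons")
        for cds in self.cds_segments:
            if not any(exon.contains(cds) for exon in self.exons):
                raise GenomeValidationError(
                    f"{self.gene_id}: CDS segment [{cds.start},{cds.end}) outside exons"
                )
        if self.biotype == "protein_coding" and self.cds_length < 3:
            raise GenomeValidationError(
                f"{self.gene_id}: protein_coding gene with CDS length {self.cds_length} < 3"
            )

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        """Derived inter-exon intervals, in genomic order."""
        return [
            Interval(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds_segments)


@dataclass
class AnnotatedGenome:
    """One species' sequence regions plus its gene models."""

    species_id: str
    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for region, seq in self.sequences.items():
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise GenomeValidationError(
                    f"{self.species_id}/{region}: non-ACGTN characters {sorted(bad)!r}"
                )
        for gene in self.genes:
            if gene.seq_region not in self.sequences:
                raise GenomeValidationError(
                    f"{gene.gene_id}: sequence region {gene.seq_region!r} absent from genome"
                )
            region_len = len(self.sequences[gene.seq_region])
            if gene.span.end > region_len:
                raise GenomeValidationError(
                    f"{gene.gene_id}: feature end {gene.span.end} beyond region "
                    f"length {region_len}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def protein_coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "protein_coding"]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet. Involution."""
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds_seq: str, strict: bool = False) -> str:
    """Translate a CDS with the standard genetic code; stops are '*'.

    In strict mode the length must be divisible by 3 and any codon containing
    an ambiguous base is an error; in lenient mode trailing bases are dropped
    and ambiguous codons yield 'X'.
    """
    if strict and len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_seq)} not divisible by 3")
    usable = cds_seq[: len(cds_seq) - (len(cds_seq) % 3)]
    if strict and "N" in usable:
        raise ValueError("ambiguous base inside codon in strict mode")
    return str(Seq(usable).translate())


def extract_feature_sequence(
    genome: AnnotatedGenome, gene: GeneModel, part: str = "gene"
) -> str:
    """Extract a gene part in transcription/translation orientation.

    ``part`` is one of ``gene`` (exon span incl. introns), ``cds``
    (concatenated CDS in translation order) or ``intron_k`` (k = 1-based index
    in transcription order). Minus-strand results are reverse-complemented.
    """
    region = genome.sequences[gene.seq_region]

    def cut(iv: Interval) -> str:
        return region[iv.start : iv.end]

    if part == "gene":
        raw = cut(gene.span)
        return reverse_complement(raw) if gene.strand == "-" else raw
    if part == "cds":
        pieces = [cut(iv) for iv in gene.cds_segments]
        raw = "".join(pieces)
        return reverse_complement(raw) if gene.strand == "-" else raw
    if part.startswith("intron_"):
        k = int(part.split("_", 1)[1])
        introns = gene.introns
        if gene.strand == "-":
            introns = introns[::-1]  # transcription order
        if not (1 <= k <= len(introns)):
            raise IndexError(
                f"{gene.gene_id}: intron index {k} out of range (1..{len(introns)})"
            )
        raw = cut(introns[k - 1])
        return reverse_complement(raw) if gene.strand == "-" else raw
    raise ValueError(f"unknown part {part!r}")


def gene_protein(genome: AnnotatedGenome, gene: GeneModel) -> str:
    """Protein product of a protein-coding gene (terminal '*' stripped)."""
    prot = translate(extract_feature_sequence(genome, gene, "cds"))
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _check_gff3_lines(gff3_path: str | Path) -> None:
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GffParseError(
                    f"{gff3_path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GffParseError(
                    f"{gff3_path}:{lineno}: invalid coordinate pair {start}..{end}"
                )


_BIOTYPE_ALIASES = {
    "gene": "protein_coding",
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "ncRNA": "ncRNA",
    "ncRNA_gene": "ncRNA",
}


def read_genome(
    fasta_path: str | Path, gff3_path: str | Path, species_id: str | None = None
) -> AnnotatedGenome:
    """Read one species' FASTA + GFF3 into a validated :class:`AnnotatedGenome`.

    GFF3 genes may carry multiple mRNA children; the transcript with the
    longest total CDS is retained (logged). Features on sequence regions
    absent from the FASTA are rejected.
    """
    sequences = read_fasta(fasta_path)
    _check_gff3_lines(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gff_gene in db.features_of_type(("gene", "pseudogene", "ncRNA_gene")):
        biotype = _BIOTYPE_ALIASES.get(
            gff_gene.attributes.get("biotype", [gff_gene.featuretype])[0],
            "protein_coding",
        )
        transcripts = list(db.children(gff_gene, level=1))
        best_exons: list[Interval] = []
        best_cds: list[Interval] = []
        best_len = -1
        chosen = None
        if not transcripts:
            # gene with direct exon/CDS children, or a bare feature
            exons = [
                Interval(f.start - 1, f.end) for f in db.children(gff_gene, featuretype="exon")
            ]
            cds = [
                Interval(f.start - 1, f.end) for f in db.children(gff_gene, featuretype="CDS")
            ]
            best_exons = exons or [Interval(gff_gene.start - 1, gff_gene.end)]
            best_cds = cds
        else:
            for tr in transcripts:
                exons = [
                    Interval(f.start - 1, f.end)
                    for f in db.children(tr, featuretype="exon")
                ]
                cds = [
                    Interval(f.start - 1, f.end)
                    for f in db.children(tr, featuretype="CDS")
                ]
                if not exons:
                    exons = [Interval(tr.start - 1, tr.end)]
                total = sum(len(c) for c in cds)
                if total > best_len:
                    best_len, best_exons, best_cds, chosen = total, exons, cds, tr.id
            if len(transcripts) > 1:
                logger.info(
                    "gene %s has %d transcripts; kept %s (longest CDS)",
                    gff_gene.id,
                    len(transcripts),
                    chosen,
                )
        genes.append(
            GeneModel(
                gene_id=gff_gene.id,
                seq_region=gff_gene.seqid,
                strand=gff_gene.strand if gff_gene.strand in "+-" else "+",
                exons=best_exons,
                cds_segments=best_cds,
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: (g.seq_region, g.span.start, g.gene_id))
    return AnnotatedGenome(
        species_id=species_id or Path(fasta_path).stem,
        sequences=sequences,
        genes=genes,
    )


def write_genome(
    genome: AnnotatedGenome, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Deterministic, sorted FASTA + GFF3 writer (inverse of :func:`read_genome`)."""
    write_fasta(genome.sequences, fasta_path)
    lines = ["##gff-version 3"]
    for region in sorted(genome.sequences):
        lines.append(
            f"##sequence-region {region} 1 {len(genome.sequences[region])}"
        )
    feature_type = {
        "protein_coding": "gene",
        "pseudogene": "pseudogene",
        "ncRNA": "ncRNA_gene",
    }
    for gene in sorted(genome.genes, key=lambda g: (g.seq_region, g.span.start, g.gene_id)):
        span = gene.span
        attrs = f"ID={gene.gene_id};biotype={gene.biotype}"
        lines.append(
            "\t".join(
                [
                    gene.seq_region,
                    "trgscout",
                    feature_type[gene.biotype],
                    str(span.start + 1),
                    str(span.end),
                    ".",
                    gene.strand,
                    ".",
                    attrs,
                ]
            )
        )
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            "\t".join(
                [
                    gene.seq_region,
                    "trgscout",
                    "mRNA",
                    str(span.start + 1),
                    str(span.end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={mrna_id};Parent={gene.gene_id}",
                ]
            )
        )
        for i, exon in enumerate(gene.exons, 1):
            lines.append(
                "\t".join(
                    [
                        gene.seq_region,
                        "trgscout",
                        "exon",
                        str(exon.start + 1),
                        str(exon.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={mrna_id}.exon{i};Parent={mrna_id}",
                    ]
                )
            )
        # CDS phase: number of bases to remove from the start of the segment
        # (in translation order) to reach the next codon boundary.
        segs = gene.cds_segments if gene.strand == "+" else gene.cds_segments[::-1]
        consumed = 0
        phases: dict[Interval, int] = {}
        for seg in segs:
            phases[seg] = (3 - consumed % 3) % 3
            consumed += len(seg)
        for i, cds in enumerate(gene.cds_segments, 1):
            lines.append(
                "\t".join(
                    [
                        gene.seq_region,
                        "trgscout",
                        "CDS",
                        str(cds.start + 1),
                        str(cds.end),
                        ".",
                        gene.strand,
                        str(phases[cds]),
                        f"ID={mrna_id}.cds{i};Parent={mrna_id}",
                    ]
                )
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def structural_qc_violations(genome: AnnotatedGenome) -> dict[str, list[str]]:
    """Report (never silently fix) coding-structure problems per gene.

    Downstream QC uses this; validation in this module is structural only.
    """
    report: dict[str, list[str]] = {}
    for gene in genome.protein_coding_genes:
        problems = []
        prot = translate(extract_feature_sequence(genome, gene, "cds"))
        if "*" in prot[:-1]:
            problems.append("internal_stop")
        if problems:
            report[gene.gene_id] = problems
    return report
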