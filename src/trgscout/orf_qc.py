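"""ORF detection, the outgroup ORF-conservation filter, and codified
annotation-consistency QC.

An ORF here is a maximal ATG→stop reading frame of at least
``min_orf_codons`` codons (terminal stop required, no internal stop, no N).
ORF conservation in the closest outgroups — an unannotated outgroup ORF
covering at least half of a candidate's ORF — is treated as evidence that
the family originated before the clade split, and removes the candidate.
The QC stage codifies the checks that are usually done by eye: start/stop
codons present, splice signals canonical, exon frames consistent, and
start/stop/splice positions aligned across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_io import (
    AnnotatedGenome,
    GeneModel,
    Interval,
    extract_feature_sequence,
    translate,
)
from .region_homology import AlignmentRow, RegionAlignment

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """A maximal open reading frame on the given strand of a sequence."""

    seq_id: str
    frame: int  # 0, 1, 2 — offset of the reading frame on this strand
    start: int  # position of the A of ATG
    end: int  # position just past the stop codon
    length_codons: int  # codons from ATG through stop, inclusive

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.length_codons < 1:
            raise ValueError("malformed ORF call")


def find_orfs(
    seq: str, min_orf_codons: int = 50, seq_id: str = "seq"
) -> list[OrfCall]:
    """Maximal ORFs in all three frames of the given strand.

    "Maximal" means the first ATG after the previous stop in that frame; a
    terminal stop is required (trailing start-without-stop is not called).
    Windows containing N are skipped. Deterministic order: by start, then
    frame. Callers scan the reverse complement themselves when both
    orientations are wanted.
    """
    calls: list[OrfCall] = []
    for frame in range(3):
        start: Optional[int] = None
        has_n = False
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                has_n = True
            if start is None:
                if codon == "ATG":
                    start = pos
                    has_n = "N" in codon
            elif codon in STOP_CODONS:
                n_codons = (pos + 3 - start) // 3
                if n_codons >= min_orf_codons and not has_n:
                    calls.append(
                        OrfCall(
                            seq_id=seq_id,
                            frame=frame,
                            start=start,
                            end=pos + 3,
                            length_codons=n_codons,
                        )
                    )
                start = None
                has_n = False
    calls.sort(key=lambda c: (c.start, c.frame))
    return calls


# ---------------------------------------------------------------------------
# Outgroup ORF conservation
# ---------------------------------------------------------------------------


def _orf_columns(row: AlignmentRow, orf: OrfCall) -> set[int]:
    """Alignment columns occupied by an ORF called on the row's de-gapped
    sequence."""
    cols = []
    seen = 0
    for c, ch in enumerate(row.gapped):
        if ch == "-":
            continue
        if orf.start <= seen < orf.end:
            cols.append(c)
        seen += 1
        if seen >= orf.end:
            break
    return set(cols)


def outgroup_orf_conservation(
    alignment: RegionAlignment,
    candidate_species: str,
    candidate_orf_interval: Interval,
    outgroup_species: Sequence[str],
    threshold: float = 0.5,
    min_species: int = 1,
    min_orf_codons: int = 10,
) -> tuple[bool, dict[str, float]]:
    """Does any close outgroup carry an ORF covering the candidate's ORF?

    ``candidate_orf_interval`` is the genomic interval of the candidate ORF
    in ``candidate_species``; its alignment-column span is the denominator.
    For each outgroup row, ORFs are called on the de-gapped row sequence (the
    row is already in candidate orientation), mapped back to columns, and the
    best column overlap fraction recorded. The flag is true — an earlier
    origin is indicated, and the candidate is removed — iff at least
    ``min_species`` outgroup rows reach ≥ ``threshold`` (inclusive).
    """
    c0, c1 = alignment.columns_for_genomic_interval(
        candidate_species, candidate_orf_interval
    )
    cand_cols = {
        c for c in range(c0, c1)
        if alignment.row(candidate_species).gapped[c] != "-"
    }
    evidence: dict[str, float] = {}
    for sp in outgroup_species:
        try:
            row = alignment.row(sp)
        except KeyError:
            continue
        best = 0.0
        for orf in find_orfs(row.ungapped, min_orf_codons=min_orf_codons, seq_id=sp):
            overlap = len(_orf_columns(row, orf) & cand_cols) / len(cand_cols)
            best = max(best, overlap)
        evidence[sp] = best
    n_reaching = sum(1 for v in evidence.values() if v >= threshold)
    return n_reaching >= min_species, evidence


# ---------------------------------------------------------------------------
# Splice signals and annotation QC
# ---------------------------------------------------------------------------


def splice_signal_check(genome: AnnotatedGenome, gene: GeneModel) -> list[bool]:
    """Per-intron canonical GT–AG flag (strand-aware; DNA alphabet).

    Introns shorter than 4 nt cannot carry both signals and are flagged
    non-canonical.
    """
    if not gene.introns:
        raise ValueError(f"{gene.gene_id} has no introns")
    flags = []
    n = len(gene.introns)
    for k in range(1, n + 1):
        intron = extract_feature_sequence(genome, gene, f"intron_{k}")
        flags.append(
            len(intron) >= 4 and intron[:2] == "GT" and intron[-2:] == "AG"
        )
    return flags


@dataclass
class QcReport:
    """Per-candidate annotation QC flags; fail iff any flag set."""

    family_id: str
    missing_start: list[str] = field(default_factory=list)
    missing_stop: list[str] = field(default_factory=list)
    noncanonical_splice: list[str] = field(default_factory=list)
    frame_overlapping_exons: list[str] = field(default_factory=list)
    inconsistent_start: bool = False
    inconsistent_stop: bool = False
    inconsistent_splice: bool = False
    too_few_annotated: bool = False

    @property
    def passed(self) -> bool:
        return not (
            self.missing_start
            or self.missing_stop
            or self.noncanonical_splice
            or self.frame_overlapping_exons
            or self.inconsistent_start
            or self.inconsistent_stop
            or self.inconsistent_splice
            or self.too_few_annotated
        )

    def flags(self) -> list[str]:
        out = []
        for sp in self.missing_start:
            out.append(f"missing_start:{sp}")
        for sp in self.missing_stop:
            out.append(f"missing_stop:{sp}")
        for sp in self.noncanonical_splice:
            out.append(f"noncanonical_splice:{sp}")
        for sp in self.frame_overlapping_exons:
            out.append(f"frame_overlapping_exons:{sp}")
        if self.inconsistent_start:
            out.append("inconsistent_start")
        if self.inconsistent_stop:
            out.append("inconsistent_stop")
        if self.inconsistent_splice:
            out.append("inconsistent_splice")
        if self.too_few_annotated:
            out.append("too_few_annotated")
        return out


def _cds_boundary_positions(gene: GeneModel) -> tuple[int, int]:
    """Plus-strand genomic positions of the first and last CDS base in
    translation order."""
    if gene.strand == "+":
        return gene.cds_segments[0].start, gene.cds_segments[-1].end - 1
    return gene.cds_segments[-1].end - 1, gene.cds_segments[0].start


def annotation_consistency(
    candidate_family,
    genomes: dict[str, AnnotatedGenome],
    alignment: Optional[RegionAlignment] = None,
    column_slack: int = 0,
    min_annotated_species: int = 2,
) -> QcReport:
    """Codified annotation QC for one candidate family.

    Flags: CDS missing ATG start or terminal stop; non-canonical splice
    signals; annotated exons of a gene overlapping each other in different
    frames; and — when an alignment is supplied — start/stop codon columns
    or splice columns that disagree across species beyond ``column_slack``.
    A candidate must have annotation-backed members in at least
    ``min_annotated_species`` species (conservation in more than one
    independently annotated species is the functionality proxy).
    """
    report = QcReport(family_id=candidate_family.family_id)
    members = sorted(candidate_family.members)
    annotated = []
    for species_id, gene_id in members:
        genome = genomes[species_id]
        try:
            gene = genome.gene(gene_id)
        except KeyError:
            continue
        if gene.biotype != "protein_coding":
            continue
        annotated.append((species_id, gene))
    if len({sp for sp, _ in annotated}) < min_annotated_species:
        report.too_few_annotated = True
    start_cols, stop_cols, splice_cols = [], [], []
    for species_id, gene in annotated:
        genome = genomes[species_id]
        cds = extract_feature_sequence(genome, gene, "cds")
        if not cds.startswith("ATG"):
            report.missing_start.append(species_id)
        if cds[-3:] not in STOP_CODONS:
            report.missing_stop.append(species_id)
        else:
            prot = translate(cds)
            if "*" in prot[:-1]:
                report.missing_stop.append(species_id)  # premature stop
        if gene.introns and not all(splice_signal_check(genome, gene)):
            report.noncanonical_splice.append(species_id)
        # exon pairs overlapping in different frames (within the one gene)
        for i, a in enumerate(gene.exons):
            for b in gene.exons[i + 1 :]:
                if a.overlaps(b):
                    report.frame_overlapping_exons.append(species_id)
        if alignment is not None:
            try:
                row = alignment.row(species_id)
            except KeyError:
                continue
            first, last = _cds_boundary_positions(gene)
            col_of = {p: c for c, p in enumerate(row.coord_map) if p is not None}
            if first in col_of and last in col_of:
                start_cols.append(col_of[first])
                stop_cols.append(col_of[last])
            sp_cols = []
            for intron in gene.introns:
                for p in (intron.start, intron.end - 1):
                    if p in col_of:
                        sp_cols.append(col_of[p])
            splice_cols.append(tuple(sorted(sp_cols)))
    if alignment is not None and len(annotated) >= 2:
        if start_cols and max(start_cols) - min(start_cols) > column_slack:
            report.inconsistent_start = True
        if stop_cols and max(stop_cols) - min(stop_cols) > column_slack:
            report.inconsistent_stop = True
        if splice_cols:
            lens = {len(t) for t in splice_cols}
            if len(lens) > 1:
                report.inconsistent_splice = True
            else:
                for positions in zip(*splice_cols):
                    if max(positions) - min(positions) > column_slack:
                        report.inconsistent_splice = True
    return report


def write_qc_table(reports: Sequence[QcReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tpassed\tflags\n")
        for r in sorted(reports, key=lambda r: r.family_id):
            fh.write(f"{r.family_id}\t{r.passed}\t{','.join(r.flags()) or '-'}\n")
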