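"""Evidence assembly for the origin of a candidate TRGF: synteny context,
the intron mod-3 argument, conserved-stop-codon frame analysis, start-codon
checks in distant outgroups, and the final classification.

The frame convention follows the analysis of putative pseudogene/ancestral
ORFs: a designated anchor start codon defines the +1 frame; +2 and +3 are
the other frames on the same strand. A "conserved stop" is a gap-free
codon-column triple that is a stop codon in every row; each is assigned a
frame per row using cumulative indel offsets relative to the anchor, and
codons whose frame assignment differs between rows are reported as
frame-ambiguous rather than counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_io import AnnotatedGenome, Interval
from .orf_qc import STOP_CODONS
from .region_homology import RegionAlignment
from .similarity_search import ScoringScheme, intragenomic_duplicates

Classification = str  # de_novo | earlier_origin | diverged_ancestor | undetermined


@dataclass(frozen=True)
class FrameConvention:
    """Anchor row + anchor column (a designated start codon) defining the
    +1/+2/+3 frame labels on the anchor strand."""

    anchor_species: str
    anchor_column: int  # alignment column of the first base of the anchor codon

    def frame_label(self, offset_mod3: int) -> str:
        return {0: "+1", 1: "+2", 2: "+3"}[offset_mod3 % 3]


@dataclass
class SyntenyReport:
    per_species_flanks: dict[str, list[str]]  # species -> flanking family ids
    shared_families: set[str]
    synteny_ok: bool


@dataclass
class OriginEvidence:
    family_id: str
    synteny: Optional[SyntenyReport] = None
    outgroup_orf_flag: Optional[bool] = None
    outgroup_orf_evidence: dict[str, float] = field(default_factory=dict)
    alignment_continuous: Optional[dict[str, bool]] = None
    outgroup_max_identity: Optional[float] = None
    distant_outgroup_start_codons: dict[str, str] = field(default_factory=dict)
    intron_tests: dict[int, str] = field(default_factory=dict)
    frame_analysis: Optional[dict] = None
    intragenomic_duplicate_flags: dict[str, int] = field(default_factory=dict)
    classification: Classification = "undetermined"
    rationale: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------


def synteny_context(
    candidate_family,
    regions: dict[str, tuple[str, Interval]],
    genomes: dict[str, AnnotatedGenome],
    gene_to_family: dict[tuple[str, str], str],
    window_genes: int = 3,
    quorum: float = 1.0,
) -> SyntenyReport:
    """Flanking-homolog agreement around each species' homologous region.

    ``regions`` maps species → (seq_region, interval) of its homologous
    region. For each species the nearest ``window_genes`` annotated genes
    up- and downstream are listed (a host gene whose intron contains the
    region counts as flanking context) and mapped to family ids.
    ``synteny_ok`` is true iff at least one flanking family is shared by a
    ``quorum`` fraction of the species that have alignable regions.
    """
    member_ids = {gid for _, gid in candidate_family.members}
    per_species: dict[str, list[str]] = {}
    for species, (seq_region, interval) in sorted(regions.items()):
        genome = genomes[species]
        up, down, host = [], [], []
        for gene in sorted(
            (g for g in genome.genes if g.seq_region == seq_region),
            key=lambda g: g.span.start,
        ):
            if gene.gene_id in member_ids:
                continue
            if gene.span.end <= interval.start:
                up.append(gene)
            elif gene.span.start >= interval.end:
                down.append(gene)
            elif any(i.contains(interval) for i in gene.introns) or gene.span.contains(
                interval
            ):
                host.append(gene)
        context = up[-window_genes:] + host + down[:window_genes]
        fams = []
        for gene in context:
            fam = gene_to_family.get((species, gene.gene_id))
            if fam is not None:
                fams.append(fam)
        per_species[species] = fams
    if per_species:
        counts: dict[str, int] = {}
        for fams in per_species.values():
            for fam in set(fams):
                counts[fam] = counts.get(fam, 0) + 1
        need = max(1, int(round(quorum * len(per_species))))
        shared = {fam for fam, n in counts.items() if n >= need}
    else:
        shared = set()
    return SyntenyReport(
        per_species_flanks=per_species,
        shared_families=shared,
        synteny_ok=bool(shared),
    )


# ---------------------------------------------------------------------------
# Intron mod-3 test
# ---------------------------------------------------------------------------


def intron_mod3_test(intron_length_nt: int) -> str:
    """An intron whose length is not a multiple of 3 likely predates the ORF:
    intronization after ORF birth would have caused a frameshift. Multiples
    of 3 are inconclusive — NOT evidence of later intronization."""
    if intron_length_nt < 4:
        raise ValueError("intron shorter than 4 nt cannot carry splice sites")
    return "predates_orf" if intron_length_nt % 3 != 0 else "inconclusive"


# ---------------------------------------------------------------------------
# Conserved-stop frame analysis
# ---------------------------------------------------------------------------


def conserved_stop_frames(
    alignment: RegionAlignment,
    frame_convention: FrameConvention,
    interval_columns: tuple[int, int],
) -> dict:
    """Count stop codons conserved across ALL rows, per frame.

    A conserved stop is a triple of consecutive columns, gap-free in every
    row, that spells a stop codon in every row. Its frame is computed per
    row as the number of that row's non-gap characters between the anchor
    column and the codon start, mod 3 (cumulative indel offsets shift this
    count). If rows disagree on the frame, the codon is reported as
    frame-ambiguous and not counted for any frame.

    Returns {"counts": {"+1": n, "+2": n, "+3": n}, "ambiguous": [cols],
    "open_frames": {...}, "stop_columns": {frame: [cols]}}.
    """
    c0, c1 = interval_columns
    anchor_col = frame_convention.anchor_column
    rows = alignment.rows
    counts = {"+1": 0, "+2": 0, "+3": 0}
    stop_columns: dict[str, list[int]] = {"+1": [], "+2": [], "+3": []}
    ambiguous: list[int] = []

    def row_offset(row, col: int) -> int:
        """Non-gap chars of this row in [anchor_col, col) (negative span
        counts backwards), mod 3."""
        if col >= anchor_col:
            n = sum(1 for ch in row.gapped[anchor_col:col] if ch != "-")
            return n % 3
        n = sum(1 for ch in row.gapped[col:anchor_col] if ch != "-")
        return (-n) % 3

    for c in range(c0, min(c1 - 2, alignment.n_columns - 2)):
        triple_ok = all(
            "-" not in row.gapped[c : c + 3] for row in rows
        )
        if not triple_ok:
            continue
        if not all(row.gapped[c : c + 3] in STOP_CODONS for row in rows):
            continue
        frames = {row_offset(row, c) for row in rows}
        if len(frames) == 1:
            label = frame_convention.frame_label(frames.pop())
            counts[label] += 1
            stop_columns[label].append(c)
        else:
            ambiguous.append(c)
    open_frames = {f for f, n in counts.items() if n == 0}
    return {
        "counts": counts,
        "ambiguous": ambiguous,
        "open_frames": open_frames,
        "stop_columns": stop_columns,
    }


# ---------------------------------------------------------------------------
# Distant-outgroup start-codon check
# ---------------------------------------------------------------------------


def distant_outgroup_start_check(
    alignment: RegionAlignment,
    candidate_species: str,
    candidate_start_position: int,
    distant_outgroups: Sequence[str],
    column_slack: int = 30,
) -> dict[str, str]:
    """Per distant outgroup: is an in-frame ATG present near the candidate's
    mapped start codon (± ``column_slack`` columns, in the candidate's
    frame)? Absence supports de novo birth; presence weakens it; a species
    with no alignable row is "unavailable"."""
    cand_row = alignment.row(candidate_species)
    col_of = {p: c for c, p in enumerate(cand_row.coord_map) if p is not None}
    if candidate_start_position not in col_of:
        raise ValueError("candidate start position does not map into the alignment")
    start_col = col_of[candidate_start_position]
    out: dict[str, str] = {}
    for sp in distant_outgroups:
        try:
            row = alignment.row(sp)
        except KeyError:
            out[sp] = "unavailable"
            continue
        found = False
        lo = max(0, start_col - column_slack)
        hi = min(alignment.n_columns - 2, start_col + column_slack)
        for c in range(lo, hi + 1):
            if "-" in row.gapped[c : c + 3] or "-" in cand_row.gapped[c : c + 3]:
                continue
            # in the candidate's frame: whole codons of the candidate row
            cand_off = sum(
                1 for ch in cand_row.gapped[min(start_col, c) : max(start_col, c)]
                if ch != "-"
            )
            if cand_off % 3 != 0:
                continue
            if row.gapped[c : c + 3] == "ATG":
                found = True
                break
        out[sp] = "present" if found else "absent"
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_origin(
    evidence: OriginEvidence, conserved_identity_threshold: float = 0.9
) -> OriginEvidence:
    """Apply the decision table to assembled evidence (mutates and returns).

    (a) conserved outgroup ORF → earlier_origin;
    (b) no continuous outgroup alignment → undetermined;
    (c) alignable outgroup regions noncoding + synteny ok + no distant
        in-frame start + no unexplained intragenomic duplicates → de_novo;
    (d) an extremely well-conserved outgroup row (identity ≥
        ``conserved_identity_threshold``) sharing its only stop-free frame
        with the candidate (per the conserved-stop analysis) →
        diverged_ancestor: an ancestral ORF, possibly truncated, not de novo
        birth. The frame pattern alone is not enough — a genuinely de novo
        ORF also leaves its alternate-frame stops conserved — so the
        near-identity requirement is the discriminator;
    conflicts → undetermined with explicit rationale. A "present" distant
    start codon always blocks de_novo (conservative downgrade).
    """
    ev = evidence
    ev.rationale = []
    if ev.outgroup_orf_flag:
        ev.classification = "earlier_origin"
        ev.rationale.append(
            "conserved outgroup ORF covers the candidate ORF: family predates the clade"
        )
        return ev
    continuous = ev.alignment_continuous or {}
    outgroup_rows = [sp for sp in continuous if sp != "__candidate__"]
    if not outgroup_rows or not any(continuous[sp] for sp in outgroup_rows):
        ev.classification = "undetermined"
        ev.rationale.append(
            "no continuous alignment of homologous outgroup regions obtainable"
        )
        return ev
    if ev.frame_analysis is not None and ev.outgroup_max_identity is not None:
        counts = ev.frame_analysis["counts"]
        frame_shared = (
            counts.get("+1", 1) == 0
            and (counts.get("+2", 0) + counts.get("+3", 0)) >= 2
        )
        if frame_shared and ev.outgroup_max_identity >= conserved_identity_threshold:
            ev.classification = "diverged_ancestor"
            ev.rationale.append(
                "outgroup region nearly identical to the candidate and sharing "
                "its only conserved-stop-free frame: ancestral ORF (possibly "
                "truncated), not de novo birth"
            )
            return ev
    if any(v == "present" for v in ev.distant_outgroup_start_codons.values()):
        ev.classification = "undetermined"
        ev.rationale.append(
            "in-frame start codon present in a distant outgroup: cannot rule "
            "out pseudogenized ancestral gene"
        )
        return ev
    if ev.synteny is not None and not ev.synteny.synteny_ok:
        ev.classification = "undetermined"
        ev.rationale.append("flanking synteny not conserved; homology uncertain")
        return ev
    if any(n > 0 for n in ev.intragenomic_duplicate_flags.values()):
        ev.classification = "undetermined"
        ev.rationale.append(
            "outgroup region has intragenomic duplicates: possible duplication "
            "followed by loss"
        )
        return ev
    ev.classification = "de_novo"
    ev.rationale.append(
        "outgroup homologous regions are noncoding (no conserved ORF), synteny "
        "conserved, no distant in-frame start codon, no duplicate confounders"
    )
    if ev.intron_tests:
        predating = [k for k, v in ev.intron_tests.items() if v == "predates_orf"]
        if predating:
            ev.rationale.append(
                f"intron(s) {predating} have length not divisible by 3: "
                "likely predate the ORF"
            )
    return ev


def collect_intragenomic_duplicates(
    regions: dict[str, tuple[str, Interval]],
    genomes: dict[str, AnnotatedGenome],
    scheme: ScoringScheme,
    skip_species: Sequence[str] = (),
    max_e: float = 1e-3,
    min_cov: float = 0.5,
) -> dict[str, int]:
    """Count non-self hits of each species' homologous region within its own
    genome (duplication-and-loss risk)."""
    out: dict[str, int] = {}
    for sp, (region, iv) in sorted(regions.items()):
        if sp in skip_species:
            continue
        hits = intragenomic_duplicates(
            (region, iv), genomes[sp], scheme, max_e=max_e, min_cov=min_cov
        )
        out[sp] = len(hits)
    return out
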