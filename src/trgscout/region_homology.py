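"""Homologous DNA regions for candidate families: locating them in every
genome, aligning them, and measuring identity/continuity.

The nucleotide search uses two query forms per candidate gene — the whole
gene sequence and the concatenated CDS — so that short coding exons are not
lost when the intron/UTR signal is weak, and vice versa. Hits are filtered
(e ≤ 1e-03, coverage ≥ 50% per query form), amalgamated and capped, and the
member gene's own locus is always included as the self-hit row.

The multiple alignment is a deterministic reference-anchored star alignment:
each region is aligned semi-globally to the candidate self-hit row and the
pairwise gap patterns are merged. Rows found on the minus strand are
reverse-complemented before alignment and flagged. Every row carries a
column → genomic-position map; de-gapping a row always reproduces the
extracted genomic substring (strand-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .genome_io import AnnotatedGenome, Interval, extract_feature_sequence, reverse_complement
from .similarity_search import (
    RegionHit,
    ScoringScheme,
    amalgamate_hits,
    cap_hits,
    default_nucleotide_scheme,
    search,
)


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentRow:
    species_id: str
    seq_region: str
    interval: Interval  # plus-strand genomic coordinates
    strand: str
    gapped: str
    # column -> genomic position (plus-strand) or None at gaps; for minus-
    # strand rows positions run downstream (descending in plus coordinates).
    coord_map: list[Optional[int]] = field(default_factory=list)

    @property
    def ungapped(self) -> str:
        return self.gapped.replace("-", "")

    def ungapped_index(self, column: int) -> int:
        """Number of non-gap characters strictly before ``column``."""
        return sum(1 for c in self.gapped[:column] if c != "-")


@dataclass
class RegionAlignment:
    rows: list[AlignmentRow]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].gapped) if self.rows else 0

    def row(self, species_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.species_id == species_id:
                return r
        raise KeyError(species_id)

    @property
    def species(self) -> list[str]:
        return [r.species_id for r in self.rows]

    def validate(self, genomes: dict[str, AnnotatedGenome]) -> None:
        """De-gapping and coordinate-map invariants."""
        for r in self.rows:
            if len(r.gapped) != self.n_columns:
                raise AlignmentError("ragged alignment rows")
            if len(r.coord_map) != self.n_columns:
                raise AlignmentError("coordinate map length mismatch")
            genome = genomes[r.species_id]
            sub = genome.sequences[r.seq_region][r.interval.start : r.interval.end]
            if r.strand == "-":
                sub = reverse_complement(sub)
            if r.ungapped != sub:
                raise AlignmentError(
                    f"row {r.species_id} does not reproduce its genomic substring"
                )
            positions = [p for p in r.coord_map if p is not None]
            step = 1 if r.strand == "+" else -1
            if any(b - a != step for a, b in zip(positions, positions[1:])):
                raise AlignmentError(f"non-monotone coordinate map in {r.species_id}")

    def columns_for_genomic_interval(
        self, species_id: str, interval: Interval
    ) -> tuple[int, int]:
        """Half-open column range covering a plus-strand genomic interval of
        one row (its non-gap columns)."""
        row = self.row(species_id)
        cols = [
            c for c, p in enumerate(row.coord_map)
            if p is not None and interval.start <= p < interval.end
        ]
        if not cols:
            raise AlignmentError("interval does not map into the alignment")
        return cols[0], cols[-1] + 1


# ---------------------------------------------------------------------------
# Region search
# ---------------------------------------------------------------------------


def find_homologous_regions(
    candidate_family,
    genomes: dict[str, AnnotatedGenome],
    scheme: Optional[ScoringScheme] = None,
    max_e: float = 1e-3,
    min_cov: float = 0.5,
    extension_flank: int = 500,
    total_limit: int = 1000,
    per_species_keep: int = 5,
) -> dict[str, list[RegionHit]]:
    """Per-species nucleotide hits for a candidate family.

    For each member gene both the whole gene sequence and the concatenated
    CDS are used as queries; filters apply per query form, then hits are
    amalgamated per region/strand and capped. The member gene's own locus is
    guaranteed present as a self-hit. Hits lying wholly inside an intron of
    an annotated non-member gene are dropped (codified curation), except
    where they overlap a member gene; hits that end in the middle of the
    query gene are extended on the subject side by the missing query length
    (bounded by ``extension_flank``) so truncated homologous regions are
    recovered in full.
    """
    scheme = scheme or default_nucleotide_scheme()
    members = sorted(candidate_family.members)
    member_ids = {gid for _, gid in members}
    all_hits: list[RegionHit] = []
    for species_id, gene_id in members:
        genome = genomes.get(species_id)
        if genome is None or gene_id not in {g.gene_id for g in genome.genes}:
            raise KeyError(f"member gene {species_id}/{gene_id} missing from genomes")
        gene = genome.gene(gene_id)
        queries = {
            f"{species_id}:{gene_id}:gene": extract_feature_sequence(genome, gene, "gene"),
        }
        cds = extract_feature_sequence(genome, gene, "cds")
        if cds and cds != queries[f"{species_id}:{gene_id}:gene"]:
            queries[f"{species_id}:{gene_id}:cds"] = cds
        for qid, qseq in queries.items():
            all_hits.extend(
                search(
                    qseq, genomes.values(), scheme, query_id=qid,
                    max_e=max_e, min_cov=min_cov,
                )
            )
        # guarantee the self-hit row
        span = gene.span
        all_hits.append(
            RegionHit(
                query_id=f"{species_id}:{gene_id}:gene",
                query_interval=Interval(0, len(span)),
                query_length=len(span),
                subject_genome=species_id,
                seq_region=gene.seq_region,
                interval=span,
                strand="+" if gene.strand == "+" else "-",
                score=float(len(span)),
                e_value=0.0,
            )
        )
    all_hits = _drop_intronic_hits(all_hits, genomes, member_ids)
    all_hits = _extend_partial_hits(
        all_hits, genomes, member_ids, extension_flank
    )
    merged = amalgamate_hits(all_hits)
    merged = cap_hits(merged, total_limit=total_limit, per_species_keep=per_species_keep)
    per_species: dict[str, list[RegionHit]] = {sp: [] for sp in genomes}
    for h in merged:
        per_species.setdefault(h.subject_genome, []).append(h)
    return per_species


def _member_spans(genomes, member_ids):
    spans = []
    for genome in genomes.values():
        for g in genome.genes:
            if g.gene_id in member_ids:
                spans.append((genome.species_id, g.seq_region, g.span))
    return spans


def _drop_intronic_hits(hits, genomes, member_ids):
    """Codified manual curation: discard hits wholly inside an intron of an
    annotated gene that is not a candidate member."""
    out = []
    for h in hits:
        genome = genomes.get(h.subject_genome)
        drop = False
        if genome is not None:
            for gene in genome.genes:
                if gene.gene_id in member_ids or gene.seq_region != h.seq_region:
                    continue
                if any(intron.contains(h.interval) for intron in gene.introns):
                    drop = True
                    break
        if not drop:
            out.append(h)
    return out


def _extend_partial_hits(hits, genomes, member_ids, flank, pad=30):
    """Codified hit extension: a hit that ends in the middle of the query
    gene is grown on the subject side by the missing query length (plus a
    small indel allowance), up to ``flank`` per side, so the full homologous
    region enters the alignment."""
    from dataclasses import replace

    del member_ids  # extension is driven by query coverage alone
    out = []
    for h in hits:
        missing_left = h.query_interval.start
        missing_right = h.query_length - h.query_interval.end
        if h.strand == "-":
            missing_left, missing_right = missing_right, missing_left
        grow_left = min(flank, missing_left + pad) if missing_left > 0 else 0
        grow_right = min(flank, missing_right + pad) if missing_right > 0 else 0
        if grow_left or grow_right:
            region_len = len(genomes[h.subject_genome].sequences[h.seq_region])
            h = replace(
                h,
                interval=Interval(
                    max(0, h.interval.start - grow_left),
                    min(region_len, h.interval.end + grow_right),
                ),
            )
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Star multiple alignment with coordinate maps
# ---------------------------------------------------------------------------


def _semiglobal_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _pairwise_gapped(aligner, ref: str, other: str) -> tuple[str, str]:
    aln = next(iter(aligner.align(ref, other)))
    blocks_r, blocks_o = aln.aligned
    sr, so = [], []
    pr = po = 0
    for (ra, rb), (oa, ob) in zip(blocks_r, blocks_o):
        if ra > pr:
            sr.append(ref[pr:ra])
            so.append("-" * (ra - pr))
        if oa > po:
            sr.append("-" * (oa - po))
            so.append(other[po:oa])
        sr.append(ref[ra:rb])
        so.append(other[oa:ob])
        pr, po = rb, ob
    if pr < len(ref) or po < len(other):
        tail_r = ref[pr:]
        tail_o = other[po:]
        sr.append(tail_r + "-" * len(tail_o))
        so.append("-" * len(tail_r) + tail_o)
    return "".join(sr), "".join(so)


def align_regions(
    region_hits: Sequence[RegionHit],
    genomes: dict[str, AnnotatedGenome],
    scheme: Optional[ScoringScheme] = None,
    reference: Optional[RegionHit] = None,
) -> RegionAlignment:
    """Star-align the hit regions around a reference row.

    The reference defaults to the first hit (callers pass the candidate
    self-hit). Minus-strand regions are reverse-complemented before
    alignment. The produced :class:`RegionAlignment` satisfies the de-gap
    and coordinate-map invariants (checked via ``validate``).
    """
    hits = list(region_hits)
    if len(hits) < 2:
        raise AlignmentError("need at least two regions to align")
    scheme = scheme or default_nucleotide_scheme()
    ref_hit = reference if reference is not None else hits[0]
    ordered = [ref_hit] + [h for h in hits if h is not ref_hit]

    def extract(h: RegionHit) -> str:
        seq = genomes[h.subject_genome].sequences[h.seq_region][
            h.interval.start : h.interval.end
        ]
        return reverse_complement(seq) if h.strand == "-" else seq

    seqs = [extract(h) for h in ordered]
    aligner = _semiglobal_aligner(scheme)

    # progressive merge of pairwise alignments to the reference
    master_ref = seqs[0]  # with insertions accumulated as gaps
    rows_gapped: list[str] = [seqs[0]]
    for other in seqs[1:]:
        ref_g, oth_g = _pairwise_gapped(aligner, master_ref.replace("-", ""), other)
        # re-inject the master's existing gap columns into the new pair
        merged_ref, merged_oth, merged_rows = _merge_into_master(
            master_ref, rows_gapped, ref_g, oth_g
        )
        master_ref = merged_ref
        rows_gapped = merged_rows + [merged_oth]
    result_rows = []
    for h, gapped in zip(ordered, rows_gapped):
        coord_map: list[Optional[int]] = []
        if h.strand == "+":
            pos = h.interval.start
            for c in gapped:
                if c == "-":
                    coord_map.append(None)
                else:
                    coord_map.append(pos)
                    pos += 1
        else:
            pos = h.interval.end - 1
            for c in gapped:
                if c == "-":
                    coord_map.append(None)
                else:
                    coord_map.append(pos)
                    pos -= 1
        result_rows.append(
            AlignmentRow(
                species_id=h.subject_genome,
                seq_region=h.seq_region,
                interval=h.interval,
                strand=h.strand,
                gapped=gapped,
                coord_map=coord_map,
            )
        )
    alignment = RegionAlignment(rows=result_rows)
    alignment.validate(genomes)
    return alignment


def _merge_into_master(
    master_ref: str, rows: list[str], ref_g: str, oth_g: str
) -> tuple[str, str, list[str]]:
    """Merge a new pairwise (ref, other) alignment into the running master
    alignment keyed on the shared ungapped reference."""
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_oth: list[str] = []
    i = j = 0  # i over master columns, j over pair columns
    Lm, Lp = len(master_ref), len(ref_g)
    while i < Lm or j < Lp:
        m_char = master_ref[i] if i < Lm else None
        p_char = ref_g[j] if j < Lp else None
        if m_char == "-" and (p_char != "-" or j >= Lp):
            # master-only insertion column: other row gets a gap
            out_master.append("-")
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_oth.append("-")
            i += 1
        elif p_char == "-" or i >= Lm:
            # pair-only insertion column (other inserted vs ref)
            out_master.append("-")
            for k in range(len(rows)):
                out_rows[k].append("-")
            out_oth.append(oth_g[j])
            j += 1
        else:
            out_master.append(m_char)
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_oth.append(oth_g[j])
            i += 1
            j += 1
    return (
        "".join(out_master),
        "".join(out_oth),
        ["".join(r) for r in out_rows],
    )


# ---------------------------------------------------------------------------
# Identity and continuity
# ---------------------------------------------------------------------------


def percent_identity(
    alignment: RegionAlignment,
    row_a: str,
    row_b: str,
    exclude_indels: bool = True,
) -> tuple[float, dict[str, int]]:
    """Pairwise identity between two rows.

    Returns (identity, counts) where identity = matches / aligned non-gap
    columns; ``counts`` reports matches, compared columns, excluded indel
    columns (a gap in exactly one of the two rows) and total columns.
    """
    a = alignment.row(row_a).gapped
    b = alignment.row(row_b).gapped
    matches = compared = indels = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            indels += 1
            if not exclude_indels:
                compared += 1
            continue
        compared += 1
        if x == y:
            matches += 1
    identity = matches / compared if compared else 0.0
    return identity, {
        "matches": matches,
        "compared_columns": compared,
        "indel_columns": indels,
        "total_columns": len(a),
    }


def is_continuous(
    alignment: RegionAlignment,
    candidate_species: str,
    candidate_interval: Interval,
    min_cover: float = 0.8,
    max_gap_block: int = 50,
) -> dict[str, bool]:
    """Operational "continuous alignment" test per row.

    A row is continuous over the candidate gene's alignment span when it
    covers ≥ ``min_cover`` of that span with no gap block longer than
    ``max_gap_block`` columns. Both thresholds are declared defaults.
    """
    c0, c1 = alignment.columns_for_genomic_interval(
        candidate_species, candidate_interval
    )
    span = c1 - c0
    out: dict[str, bool] = {}
    for row in alignment.rows:
        seg = row.gapped[c0:c1]
        non_gap = sum(1 for ch in seg if ch != "-")
        longest_gap = 0
        run = 0
        for ch in seg:
            run = run + 1 if ch == "-" else 0
            longest_gap = max(longest_gap, run)
        out[row.species_id] = (
            non_gap / span >= min_cover and longest_gap <= max_gap_block
        )
    return out


def write_alignment(alignment: RegionAlignment, fasta_path, map_path) -> None:
    """Aligned FASTA plus a sidecar TSV of row coordinate maps."""
    with open(fasta_path, "w") as fh:
        for row in alignment.rows:
            fh.write(
                f">{row.species_id} {row.seq_region}:{row.interval.start}-"
                f"{row.interval.end}({row.strand})\n{row.gapped}\n"
            )
    with open(map_path, "w") as fh:
        fh.write("species\tcolumn\tgenomic_position\n")
        for row in alignment.rows:
            for col, pos in enumerate(row.coord_map):
                fh.write(f"{row.species_id}\t{col}\t{'' if pos is None else pos}\n")
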