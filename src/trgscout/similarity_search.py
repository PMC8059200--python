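"""Seeded Smith–Waterman search with Karlin–Altschul significance and the
hit post-processing rules: e-value ≤ 1e-03 and query coverage ≥ 50% filters,
amalgamation of overlapping hits, and the 1,000-hit / best-5-per-species cap.

This module is the in-repo stand-in for BlastP/BlastN: exact k-mer seeds
(k=11 nucleotide, k=4 protein) locate candidate regions, which are then
aligned with an affine-gap local dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import AnnotatedGenome, Interval, reverse_complement

# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores + affine gap penalties + Karlin–Altschul λ, K.

    A gap of length L costs ``gap_open + gap_extend * L``. λ and K are
    tabulated gapped constants for the default parameterizations; the
    e-value uses the ungapped Karlin–Altschul form with these constants.
    """

    alphabet: str  # "protein" | "nucleotide"
    matrix: object  # Bio.Align substitution matrix
    gap_open: float
    gap_extend: float
    lambda_: float
    k_param: float
    seed_k: int
    _aligner: object = field(default=None, init=False, repr=False, compare=False)

    def aligner(self) -> Align.PairwiseAligner:
        # per-instance lazy engine (frozen dataclass, hence object.__setattr__)
        if self._aligner is None:
            aligner = Align.PairwiseAligner()
            aligner.mode = "local"
            aligner.substitution_matrix = self.matrix
            aligner.open_gap_score = -(self.gap_open + self.gap_extend)
            aligner.extend_gap_score = -self.gap_extend
            object.__setattr__(self, "_aligner", aligner)
        return self._aligner


def _nucleotide_matrix(match: float = 1.0, mismatch: float = -2.0):
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


def default_nucleotide_scheme() -> ScoringScheme:
    # +1/−2 with gap 5/2; tabulated gapped λ, K for this scheme
    return ScoringScheme(
        alphabet="nucleotide",
        matrix=_nucleotide_matrix(),
        gap_open=5.0,
        gap_extend=2.0,
        lambda_=1.28,
        k_param=0.46,
        seed_k=11,
    )


def default_protein_scheme() -> ScoringScheme:
    blosum = substitution_matrices.load("BLOSUM62")
    return ScoringScheme(
        alphabet="protein",
        matrix=blosum,
        gap_open=11.0,
        gap_extend=1.0,
        lambda_=0.267,
        k_param=0.041,
        seed_k=4,
    )


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    a_interval: Interval
    b_interval: Interval
    aligned_a: str
    aligned_b: str

    @property
    def length(self) -> int:
        """Number of alignment columns (including gap columns)."""
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return matches / self.length if self.length else 0.0


EMPTY_ALIGNMENT = LocalAlignment(0.0, Interval(0, 0), Interval(0, 0), "", "")


def _scheme_alphabet_chars(scheme: ScoringScheme) -> set[str]:
    return set(str(scheme.matrix.alphabet))


def smith_waterman_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Score of the best local alignment only (cheaper than a full traceback)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    score = scheme.aligner().score(a, b)
    return float(score) if score > 0 else 0.0


def smith_waterman(a: str, b: str, scheme: ScoringScheme) -> LocalAlignment:
    """Best affine-gap local alignment of ``a`` vs ``b``.

    Returns the empty alignment (score 0) when no positive-scoring cell
    exists. The optimal alignment reported is the engine's first, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    allowed = _scheme_alphabet_chars(scheme)
    bad = (set(a) | set(b)) - allowed
    if bad:
        raise ValueError(f"characters {sorted(bad)!r} outside scheme alphabet")
    aligner = scheme.aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return EMPTY_ALIGNMENT
    aln = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    # build gapped strings from aligned blocks
    sa, sb = [], []
    prev_a, prev_b = a_start, b_start
    for (xa, ya), (xb, yb) in zip(blocks_a, blocks_b):
        if xa > prev_a:
            sa.append(a[prev_a:xa])
            sb.append("-" * (xa - prev_a))
        if xb > prev_b:
            sa.append("-" * (xb - prev_b))
            sb.append(b[prev_b:xb])
        sa.append(a[xa:ya])
        sb.append(b[xb:yb])
        prev_a, prev_b = ya, yb
    return LocalAlignment(
        score=float(score),
        a_interval=Interval(a_start, a_end),
        b_interval=Interval(b_start, b_end),
        aligned_a="".join(sa),
        aligned_b="".join(sb),
    )


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search space sizes must be positive")
    return scheme.k_param * m * n * math.exp(-scheme.lambda_ * score)


# ---------------------------------------------------------------------------
# RegionHit + seeded genome search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionHit:
    """A located similarity hit of a query inside a subject genome."""

    query_id: str
    query_interval: Interval
    query_length: int
    subject_genome: str
    seq_region: str
    interval: Interval
    strand: str  # strand of the subject match relative to the query
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")

    @property
    def query_coverage(self) -> float:
        return len(self.query_interval) / self.query_length


_KMER_CACHE: dict[tuple[int, int, int], dict[str, list[int]]] = {}


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    key = (hash(seq), len(seq), k)  # str hash is cached by the interpreter
    cached = _KMER_CACHE.get(key)
    if cached is not None:
        return cached
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    if len(_KMER_CACHE) > 64:
        _KMER_CACHE.clear()
    _KMER_CACHE[key] = index
    return index


def _seed_clusters(
    query: str, subject_index: dict[str, list[int]], k: int, band: int = 32
) -> list[tuple[int, int]]:
    """Cluster exact k-mer seed matches by diagonal band; return subject
    extents (smin, smax) of each cluster."""
    by_band: dict[int, list[tuple[int, int]]] = {}
    for q in range(len(query) - k + 1):
        kmer = query[q : q + k]
        for s in subject_index.get(kmer, ()):
            by_band.setdefault((s - q) // band, []).append((q, s))
    clusters: list[tuple[int, int]] = []
    seen: set[int] = set()
    for b in sorted(by_band):
        if b in seen:
            continue
        matches = list(by_band[b])
        # merge adjacent diagonal bands into one cluster
        nb = b + 1
        while nb in by_band and nb not in seen:
            matches.extend(by_band[nb])
            seen.add(nb)
            nb += 1
        seen.add(b)
        smin = min(s for _, s in matches)
        smax = max(s for _, s in matches) + k
        clusters.append((smin, smax))
    return clusters


def _window_hits(
    query: str,
    query_id: str,
    subject_seq: str,
    clusters: Sequence[tuple[int, int]],
    subject_genome: str,
    region: str,
    strand: str,
    scheme: ScoringScheme,
    db_size: int,
) -> list[RegionHit]:
    hits = []
    qlen = len(query)
    for smin, smax in clusters:
        w0 = max(0, smin - qlen)
        w1 = min(len(subject_seq), smax + qlen)
        window = subject_seq[w0:w1]
        aln = smith_waterman(query, window, scheme)
        if aln.score <= 0:
            continue
        sub_iv = Interval(w0 + aln.b_interval.start, w0 + aln.b_interval.end)
        if strand == "-":
            # map the reverse-complement coordinates back to plus strand
            L = len(subject_seq)
            sub_iv = Interval(L - sub_iv.end, L - sub_iv.start)
        hits.append(
            RegionHit(
                query_id=query_id,
                query_interval=aln.a_interval,
                query_length=qlen,
                subject_genome=subject_genome,
                seq_region=region,
                interval=sub_iv,
                strand=strand,
                score=aln.score,
                e_value=evalue(aln.score, qlen, db_size, scheme),
            )
        )
    return hits


def search(
    query: str,
    subject_db: Iterable[AnnotatedGenome],
    scheme: ScoringScheme,
    query_id: str = "query",
    max_e: float = 1e-3,
    min_cov: float = 0.5,
) -> list[RegionHit]:
    """Nucleotide search of a query against genome(s), both strands.

    Hits failing ``e_value <= max_e`` or ``query_coverage >= min_cov`` are
    dropped (both boundaries inclusive, matching the ≥50% / ≤1e-03 rules).
    Minus-strand hits are reported in plus coordinates with strand "-".
    An empty database yields an empty result.
    """
    genomes = list(subject_db)
    if not query:
        raise ValueError("query must be non-empty")
    db_size = sum(len(s) for g in genomes for s in g.sequences.values())
    if db_size == 0:
        return []
    k = scheme.seed_k
    hits: list[RegionHit] = []
    rc_query = reverse_complement(query)
    for genome in genomes:
        for region, seq in sorted(genome.sequences.items()):
            index = _kmer_index(seq, k)
            for strand, q in (("+", query), ("-", rc_query)):
                clusters = _seed_clusters(q, index, k)
                hits.extend(
                    _window_hits(
                        q, query_id, seq, clusters, genome.species_id, region,
                        strand, scheme, db_size,
                    )
                )
    kept = [
        h for h in hits if h.e_value <= max_e and h.query_coverage >= min_cov
    ]
    kept.sort(key=_hit_order)
    return kept


def search_protein(
    query: str,
    proteomes: dict[str, dict[str, str]],
    scheme: ScoringScheme,
    query_id: str = "query",
    max_e: float = 1e-3,
    min_cov: float = 0.5,
) -> list[RegionHit]:
    """Protein search of a query against per-species protein collections.

    ``proteomes`` maps species_id -> {protein_id: sequence}. Seeding uses
    exact k=4 words; candidate subjects are then fully aligned.
    """
    if not query:
        raise ValueError("query must be non-empty")
    db_size = sum(len(s) for prots in proteomes.values() for s in prots.values())
    if db_size == 0:
        return []
    k = scheme.seed_k
    query_words = {query[i : i + k] for i in range(len(query) - k + 1)}
    hits: list[RegionHit] = []
    for species in sorted(proteomes):
        for prot_id in sorted(proteomes[species]):
            subject = proteomes[species][prot_id]
            if len(subject) < k:
                continue
            if not any(subject[i : i + k] in query_words for i in range(len(subject) - k + 1)):
                continue
            aln = smith_waterman(query, subject, scheme)
            if aln.score <= 0:
                continue
            e = evalue(aln.score, len(query), db_size, scheme)
            hit = RegionHit(
                query_id=query_id,
                query_interval=aln.a_interval,
                query_length=len(query),
                subject_genome=species,
                seq_region=prot_id,
                interval=aln.b_interval,
                strand="+",
                score=aln.score,
                e_value=e,
            )
            if e <= max_e and hit.query_coverage >= min_cov:
                hits.append(hit)
    hits.sort(key=_hit_order)
    return hits


def _hit_order(h: RegionHit):
    return (
        h.e_value,
        -h.score,
        h.subject_genome,
        h.seq_region,
        h.interval.start,
        h.interval.end,
        h.strand,
    )


def amalgamate_hits(hits: Sequence[RegionHit]) -> list[RegionHit]:
    """Merge overlapping or bookended hits on the same subject region+strand.

    The merged hit keeps the minimum e-value and best score of its parts and
    recomputes query coverage from the union span of the parts' query
    intervals. Idempotent and order-invariant.
    """
    groups: dict[tuple[str, str, str], list[RegionHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_genome, h.seq_region, h.strand), []).append(h)
    merged: list[RegionHit] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda h: (h.interval.start, h.interval.end))
        current: list[RegionHit] = []
        for h in group:
            if current and h.interval.start <= current[-1].interval.end:
                current.append(h)
            else:
                if current:
                    merged.append(_merge_group(current))
                current = [h]
        if current:
            merged.append(_merge_group(current))
    merged.sort(key=_hit_order)
    return merged


def _merge_group(group: list[RegionHit]) -> RegionHit:
    if len(group) == 1:
        return group[0]
    best = min(group, key=lambda h: (h.e_value, -h.score))
    sub = Interval(
        min(h.interval.start for h in group), max(h.interval.end for h in group)
    )
    q = Interval(
        min(h.query_interval.start for h in group),
        max(h.query_interval.end for h in group),
    )
    return replace(best, interval=sub, query_interval=q)


def cap_hits(
    hits: Sequence[RegionHit], total_limit: int = 1000, per_species_keep: int = 5
) -> list[RegionHit]:
    """Apply the hit cap: if the total exceeds ``total_limit``, keep only the
    ``per_species_keep`` best hits (smallest e-value) per subject species.
    Exactly ``total_limit`` hits pass through untouched."""
    hits = list(hits)
    if len(hits) <= total_limit:
        return hits
    by_species: dict[str, list[RegionHit]] = {}
    for h in hits:
        by_species.setdefault(h.subject_genome, []).append(h)
    kept: list[RegionHit] = []
    for species in sorted(by_species):
        ranked = sorted(by_species[species], key=_hit_order)
        kept.extend(ranked[:per_species_keep])
    kept.sort(key=_hit_order)
    return kept


def intragenomic_duplicates(
    region: tuple[str, Interval],
    genome: AnnotatedGenome,
    scheme: ScoringScheme,
    max_e: float = 1e-3,
    min_cov: float = 0.5,
) -> list[RegionHit]:
    """Non-self hits of a genomic region against its own genome; flags the
    duplication-then-loss risk for the origin classifier."""
    seq_region, iv = region
    seq = genome.sequences[seq_region][iv.start : iv.end]
    hits = search(
        seq, [genome], scheme, query_id=f"{seq_region}:{iv.start}-{iv.end}",
        max_e=max_e, min_cov=min_cov,
    )
    out = []
    for h in hits:
        if h.seq_region == seq_region and h.strand == "+" and h.interval.overlaps(iv):
            continue  # self-hit
        out.append(h)
    return out


def write_hit_table(hits: Sequence[RegionHit], path) -> None:
    """BLAST outfmt-6-like TSV (deterministic order)."""
    cols = (
        "query\tsubject_genome\tsubject_region\tq_start\tq_end\ts_start\ts_end"
        "\tstrand\tscore\tevalue\tquery_coverage\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in sorted(hits, key=_hit_order):
            fh.write(
                f"{h.query_id}\t{h.subject_genome}\t{h.seq_region}\t"
                f"{h.query_interval.start}\t{h.query_interval.end}\t"
                f"{h.interval.start}\t{h.interval.end}\t{h.strand}\t"
                f"{h.score:g}\t{h.e_value:.3e}\t{h.query_coverage:.4f}\n"
            )
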