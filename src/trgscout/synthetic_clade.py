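"""Synthetic annotated-genome clades with known evolutionary history.

Generates a five-species clade shaped like the Drosophila melanogaster
subgroup study system — a focal simulans/sechellia/melanogaster-like triplet
plus a yakuba/erecta-like ingroup-outgroup pair — and evolves an ancestral
annotated genome down the tree under Jukes–Cantor substitutions and Poisson
indels. Planted events (de novo ORF birth, duplication with rapid divergence,
pseudogenization, gene loss) are recorded in a ground-truth table so that
every downstream pipeline stage can be validated against known answers.

Coding annotations are maintained through evolution: substitutions that would
destroy a start/stop codon or splice signal, or create a premature stop in an
annotated CDS, are rejected (emulating purifying selection), and indels are
confined to unannotated sequence. Unannotated homologous loci — e.g. the
noncoding progenitor of a planted de novo ORF in species where the gene was
never born — drift freely, accumulating the stop codons and frameshifts that
the downstream origin analysis looks for.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from Bio import Phylo

from .genome_io import (
    AnnotatedGenome,
    GeneModel,
    Interval,
    extract_feature_sequence,
    reverse_complement,
    translate,
)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str
    length: float  # branch above this node, expected substitutions/site
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SpeciesTree:
    """Rooted binary tree; branch lengths in expected substitutions per site."""

    root: TreeNode

    def __post_init__(self) -> None:
        names = [n.name for n in self._walk()]
        if len(names) != len(set(names)):
            raise ValueError("node labels must be unique")
        for n in self._walk():
            if n.length < 0:
                raise ValueError(f"negative branch length on {n.name}")

    def _walk(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def find(self, name: str) -> TreeNode:
        for n in self._walk():
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = Phylo.read(io.StringIO(newick), "newick")

        def convert(clade, i=[0]) -> TreeNode:
            name = clade.name or (clade.confidence if isinstance(clade.confidence, str) else None)
            if name is None:
                i[0] += 1
                name = f"node{i[0]}"
            return TreeNode(
                name=str(name),
                length=float(clade.branch_length or 0.0),
                children=[convert(c) for c in clade.clades],
            )

        return cls(root=convert(tree.root))


def default_species_tree(subst_per_time: float = 0.02) -> SpeciesTree:
    """The study clade: ((sim,sec),mel) vs (yak,ere), with split times of
    ~0.5 / ~1.4 / ~3.3 time units (yak–ere split at 1.1), scaled to
    substitutions/site by ``subst_per_time``."""
    r = subst_per_time
    sim = TreeNode("sim", 0.5 * r)
    sec = TreeNode("sec", 0.5 * r)
    simsec = TreeNode("simsec", 0.9 * r, [sim, sec])
    mel = TreeNode("mel", 1.4 * r)
    focal = TreeNode("focal", 1.9 * r, [simsec, mel])
    yak = TreeNode("yak", 1.1 * r)
    ere = TreeNode("ere", 1.1 * r)
    yakere = TreeNode("yakere", 2.2 * r, [yak, ere])
    root = TreeNode("root", 0.0, [focal, yakere])
    return SpeciesTree(root=root)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelParams:
    """Poisson indels: expected events per site = rate_factor × branch length;
    lengths geometric with the given mean."""

    rate_factor: float = 0.1
    mean_length: float = 3.0
    insertion_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.rate_factor < 0 or self.mean_length < 1:
            raise ValueError("invalid indel parameters")


_B2I = {b: i for i, b in enumerate(BASES)}


def _jc_transition(branch_length: float) -> np.ndarray:
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    P = np.full((4, 4), p_change / 3.0)
    np.fill_diagonal(P, 1.0 - p_change)
    return P


def _substitute(
    seq_codes: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-site draw from transition matrix P (N sites, code 4, stay)."""
    out = seq_codes.copy()
    u = rng.random(seq_codes.size)
    for b in range(4):
        idx = np.nonzero(seq_codes == b)[0]
        if idx.size == 0:
            continue
        cum = np.cumsum(P[b])
        out[idx] = np.searchsorted(cum, u[idx], side="right").clip(0, 3)
    return out


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _B2I.items():
        lut[ord(b)] = i
    return lut[codes].astype(np.int8)


def _decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes.astype(np.intp)].tobytes().decode()


def evolve_sequence(
    seq: str,
    branch_length: float,
    subst_rate_matrix: Optional[np.ndarray] = None,
    indel_params: Optional[IndelParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, list[tuple]]:
    """Evolve a sequence along one branch; returns (sequence, event log).

    Substitutions follow Jukes–Cantor by default, or the transition matrix
    ``expm(Q·t)`` of a supplied 4×4 rate matrix. Indels are Poisson events
    with geometric lengths, applied sequentially after substitutions. The
    event log records every mutation: ("sub", pos, old, new) with positions
    in pre-indel coordinates, then ("ins", pos, inserted) / ("del", pos,
    deleted) in current coordinates, in application order. Deterministic for
    a fixed rng state.
    """
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    if branch_length == 0 or not seq:
        return seq, []
    if subst_rate_matrix is None:
        P = _jc_transition(branch_length)
    else:
        Q = np.asarray(subst_rate_matrix, dtype=float)
        if Q.shape != (4, 4) or np.any(Q - np.diag(np.diag(Q)) < 0):
            raise ValueError("rate matrix must be 4x4 with non-negative off-diagonals")
        from scipy.linalg import expm

        P = expm(Q * branch_length)
    codes = _encode(seq)
    valid = codes < 4
    new_codes = codes.copy()
    new_codes[valid] = _substitute(codes[valid], P, rng)
    log: list[tuple] = [
        ("sub", int(i), BASES[codes[i]], BASES[new_codes[i]])
        for i in np.nonzero(new_codes != codes)[0]
    ]
    out = _decode(new_codes)
    ip = indel_params if indel_params is not None else IndelParams()
    n_indels = rng.poisson(ip.rate_factor * branch_length * len(seq))
    for _ in range(n_indels):
        length = int(rng.geometric(1.0 / ip.mean_length))
        if rng.random() < ip.insertion_prob:
            pos = int(rng.integers(0, len(out) + 1))
            ins = "".join(BASES[i] for i in rng.integers(0, 4, length))
            out = out[:pos] + ins + out[pos:]
            log.append(("ins", pos, ins))
        else:
            pos = int(rng.integers(0, max(len(out) - length, 0) + 1))
            deleted = out[pos : pos + length]
            out = out[:pos] + out[pos + length :]
            log.append(("del", pos, deleted))
    return out, log


# ---------------------------------------------------------------------------
# Planted events and ancestral genome
# ---------------------------------------------------------------------------

EventType = Literal[
    "de_novo_birth", "duplication_divergence", "pseudogenization", "gene_loss"
]


@dataclass
class EventSpec:
    """One planted evolutionary event on a named branch of the species tree.

    ``branch`` names the tree node the branch leads into; the event is
    applied at the top of that branch, before branch evolution.
    """

    locus_id: str
    event_type: EventType
    branch: str
    orf_codons: int = 120  # de novo: protein length incl. terminal stop codon
    intron_len: Optional[int] = 52  # de novo: None for intronless ORFs
    rate_multiplier: float = 15.0  # duplication: rate scaling of the copy
    source_gene: Optional[str] = None  # duplication/pseudogenization/loss target


@dataclass
class AncestralGenomeParams:
    """Shape of the ancestral genome: two-exon protein-coding genes with
    canonical GT–AG introns separated by random intergenic spacers."""

    n_genes: int = 50
    codons_min: int = 100
    codons_max: int = 200
    intron_min: int = 50
    intron_max: int = 80
    intergenic_min: int = 200
    intergenic_max: int = 500
    seq_region: str = "chr1"


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense codons (no stops)."""
    out = []
    while len(out) < n:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in STOPS and codon != "ATG":
            out.append(codon)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _make_orf(
    rng: np.random.Generator, n_codons: int, intron_len: Optional[int]
) -> tuple[str, list[Interval], list[Interval]]:
    """Build a gene sequence: ATG + sense codons + stop, optionally split by
    a canonical intron. Returns (sequence, exons, cds) in local coordinates."""
    cds = "ATG" + _random_codons(rng, n_codons - 2) + STOPS[rng.integers(0, 3)]
    if intron_len is None:
        return cds, [Interval(0, len(cds))], [Interval(0, len(cds))]
    if intron_len < 4:
        raise SimulationError("intron length must be >= 4")
    split = len(cds) // 2 + int(rng.integers(-10, 11))
    intron = "GT" + _random_seq(rng, intron_len - 4) + "AG"
    seq = cds[:split] + intron + cds[split:]
    exons = [Interval(0, split), Interval(split + intron_len, len(seq))]
    return seq, exons, exons  # exons are entirely coding


def _degrade_to_noncoding(gene_seq: str, rng: np.random.Generator) -> str:
    """Noncoding progenitor of a born ORF: same sequence, but with the start
    codon broken and stop codons planted in all three frames so that no long
    ORF survives in any frame — the realistic state of noncoding DNA."""
    seq = list(gene_seq)
    seq[0:3] = "ATA"
    L = len(seq)
    used: set[int] = set(range(0, 6)) | set(range(L - 6, L))
    for frame in range(3):
        # a stop roughly every 90 nt in this frame; anchors staggered by
        # 30 nt between frames so the three frames' stops never collide
        for anchor in range(30 + 30 * frame + frame, L - 6, 90):
            pos = anchor - ((anchor - frame) % 3)
            if any(p in used for p in range(pos, pos + 3)):
                continue
            stop = STOPS[rng.integers(0, 3)]
            seq[pos : pos + 3] = stop
            used.update(range(pos, pos + 3))
    return "".join(seq)


def build_ancestral_genome(
    params: AncestralGenomeParams, rng: np.random.Generator
) -> AnnotatedGenome:
    """Ancestral genome alone (no planted proto-loci)."""
    genome, _ = _build_ancestor(params, [], rng)
    return genome


# ---------------------------------------------------------------------------
# Evolving lineage state
# ---------------------------------------------------------------------------


@dataclass
class _Lineage:
    seqs: dict[str, str]
    genes: list[GeneModel]
    tracked: dict[str, tuple[str, int, int]]  # locus -> (region, start, end)
    multipliers: dict[str, float] = field(default_factory=dict)


def _lineage_from_genome(g: AnnotatedGenome) -> _Lineage:
    return _Lineage(
        seqs=dict(g.sequences), genes=copy.deepcopy(g.genes), tracked={}
    )


def genome_from_lineage(species_id: str, lineage: _Lineage) -> AnnotatedGenome:
    return AnnotatedGenome(
        species_id=species_id,
        sequences=dict(lineage.seqs),
        genes=copy.deepcopy(lineage.genes),
    )


def _protected_positions(lineage: _Lineage, region: str) -> np.ndarray:
    """Boolean mask of positions where substitutions are forbidden outright:
    start/stop codons and splice dinucleotides of protein-coding genes."""
    mask = np.zeros(len(lineage.seqs[region]), dtype=bool)
    for gene in lineage.genes:
        if gene.seq_region != region or gene.biotype != "protein_coding":
            continue
        segs = gene.cds_segments if gene.strand == "+" else gene.cds_segments[::-1]
        flat: list[int] = []
        for seg in segs:
            rng_pos = range(seg.start, seg.end)
            flat.extend(rng_pos if gene.strand == "+" else reversed(rng_pos))
        for p in flat[:3] + flat[-3:]:
            mask[p] = True
        for intron in gene.introns:
            mask[intron.start : intron.start + 2] = True
            mask[intron.end - 2 : intron.end] = True
    return mask


def _gene_span_mask(lineage: _Lineage, region: str, buffer: int = 2) -> np.ndarray:
    mask = np.zeros(len(lineage.seqs[region]) + 1, dtype=bool)
    for gene in lineage.genes:
        # pseudogenes/ncRNAs drift freely, indels included
        if gene.seq_region != region or gene.biotype != "protein_coding":
            continue
        span = gene.span
        mask[max(0, span.start - buffer) : span.end + buffer] = True
    return mask


def _repair_gene(lineage: _Lineage, gene: GeneModel, parent_seq: str) -> None:
    """Revert substitutions that created internal stops in an annotated CDS."""
    if gene.biotype != "protein_coding":
        return
    region = gene.seq_region
    for _ in range(8):
        genome = AnnotatedGenome.__new__(AnnotatedGenome)
        genome.species_id = "_tmp"
        genome.sequences = lineage.seqs
        genome.genes = [gene]
        cds = extract_feature_sequence(genome, gene, "cds")
        prot = translate(cds)
        internal = [i for i, aa in enumerate(prot[:-1]) if aa == "*"]
        if not internal:
            return
        # genomic positions of each CDS base, in translation order
        segs = gene.cds_segments if gene.strand == "+" else gene.cds_segments[::-1]
        flat: list[int] = []
        for seg in segs:
            r = range(seg.start, seg.end)
            flat.extend(r if gene.strand == "+" else reversed(r))
        seq = list(lineage.seqs[region])
        for codon_i in internal:
            for p in flat[3 * codon_i : 3 * codon_i + 3]:
                seq[p] = parent_seq[p]
        lineage.seqs[region] = "".join(seq)
    raise SimulationError(f"could not repair CDS of {gene.gene_id}")


def _substitute_region(
    lineage: _Lineage,
    region: str,
    branch_length: float,
    rng: np.random.Generator,
    only_span: Optional[Interval] = None,
) -> None:
    seq = lineage.seqs[region]
    parent = seq
    codes = _encode(seq)
    P = _jc_transition(branch_length)
    valid = codes < 4
    new_codes = codes.copy()
    new_codes[valid] = _substitute(codes[valid], P, rng)
    protected = _protected_positions(lineage, region)
    new_codes[protected] = codes[protected]
    if only_span is not None:
        keep = np.ones(len(seq), dtype=bool)
        keep[only_span.start : only_span.end] = False
        new_codes[keep] = codes[keep]
    lineage.seqs[region] = _decode(new_codes)
    for gene in lineage.genes:
        if gene.seq_region == region:
            _repair_gene(lineage, gene, parent)


def _shift_point(c: int, pos: int, delta: int) -> int:
    """Lift a coordinate through an indel at ``pos`` with signed length delta."""
    if delta > 0:  # insertion at pos
        return c + delta if c >= pos else c
    L = -delta  # deletion [pos, pos+L)
    if c <= pos:
        return c
    if c >= pos + L:
        return c - L
    return pos


def _lift_features(lineage: _Lineage, region: str, pos: int, delta: int) -> None:
    for gene in lineage.genes:
        if gene.seq_region != region:
            continue
        gene.exons = [
            Interval(_shift_point(iv.start, pos, delta), _shift_point(iv.end, pos, delta))
            for iv in gene.exons
        ]
        gene.cds_segments = [
            Interval(_shift_point(iv.start, pos, delta), _shift_point(iv.end, pos, delta))
            for iv in gene.cds_segments
        ]
    for locus, (reg, s, e) in list(lineage.tracked.items()):
        if reg == region:
            lineage.tracked[locus] = (
                reg,
                _shift_point(s, pos, delta),
                _shift_point(e, pos, delta),
            )


def _apply_indels(
    lineage: _Lineage,
    region: str,
    branch_length: float,
    indel_params: IndelParams,
    rng: np.random.Generator,
) -> None:
    ip = indel_params
    n = rng.poisson(ip.rate_factor * branch_length * len(lineage.seqs[region]))
    for _ in range(n):
        seq = lineage.seqs[region]
        span_mask = _gene_span_mask(lineage, region)
        length = int(rng.geometric(1.0 / ip.mean_length))
        is_ins = rng.random() < ip.insertion_prob
        placed = False
        for _attempt in range(50):
            if is_ins:
                pos = int(rng.integers(0, len(seq) + 1))
                if span_mask[pos]:
                    continue
                ins = _random_seq(rng, length)
                lineage.seqs[region] = seq[:pos] + ins + seq[pos:]
                _lift_features(lineage, region, pos, length)
            else:
                if len(seq) <= length:
                    break
                pos = int(rng.integers(0, len(seq) - length + 1))
                if span_mask[pos : pos + length + 1].any():
                    continue
                lineage.seqs[region] = seq[:pos] + seq[pos + length :]
                _lift_features(lineage, region, pos, -length)
            placed = True
            break
        # unplaceable indels are dropped silently (dense annotation)
        del placed


def _evolve_lineage(
    lineage: _Lineage,
    branch_length: float,
    indel_params: IndelParams,
    rng: np.random.Generator,
) -> None:
    if branch_length == 0:
        return
    for region in sorted(lineage.seqs):
        _substitute_region(lineage, region, branch_length, rng)
        # loci evolving at a multiplied rate (diverging duplicates)
        for gene in lineage.genes:
            mult = lineage.multipliers.get(gene.gene_id, 1.0)
            if mult > 1.0 and gene.seq_region == region:
                extra = branch_length * (mult - 1.0)
                _substitute_region(lineage, region, extra, rng, only_span=gene.span)
        _apply_indels(lineage, region, branch_length, indel_params, rng)


# ---------------------------------------------------------------------------
# Ancestor construction and event application
# ---------------------------------------------------------------------------


def _build_ancestor(
    params: AncestralGenomeParams,
    de_novo_events: list[EventSpec],
    rng: np.random.Generator,
) -> tuple[AnnotatedGenome, dict[str, dict]]:
    """Ancestral genome plus per-event payloads. For each de novo event a
    noncoding progenitor locus is planted in intergenic space between two
    conserved genes, and the clean "born" version is stored for later."""
    pieces: list[str] = []
    genes: list[GeneModel] = []
    tracked: dict[str, tuple[str, int, int]] = {}
    payload: dict[str, dict] = {}
    region = params.seq_region
    cursor = 0

    # decide after which genes the de novo progenitors sit (interior slots)
    slots: dict[int, EventSpec] = {}
    if de_novo_events:
        positions = rng.choice(
            np.arange(2, params.n_genes - 2),
            size=len(de_novo_events),
            replace=False,
        )
        for pos, ev in zip(sorted(int(p) for p in positions), de_novo_events):
            slots[pos] = ev

    for gi in range(params.n_genes):
        spacer = _random_seq(
            rng, int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
        )
        pieces.append(spacer)
        cursor += len(spacer)
        n_codons = int(rng.integers(params.codons_min, params.codons_max + 1))
        intron_len = int(rng.integers(params.intron_min, params.intron_max + 1))
        seq, exons, cds = _make_orf(rng, n_codons, intron_len)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
            L = len(seq)
            exons = sorted(
                (Interval(L - iv.end, L - iv.start) for iv in exons),
                key=lambda iv: iv.start,
            )
            cds = list(exons)
        genes.append(
            GeneModel(
                gene_id=f"g{gi:03d}",
                seq_region=region,
                strand=strand,
                exons=[Interval(iv.start + cursor, iv.end + cursor) for iv in exons],
                cds_segments=[
                    Interval(iv.start + cursor, iv.end + cursor) for iv in cds
                ],
                biotype="protein_coding",
            )
        )
        pieces.append(seq)
        cursor += len(seq)
        if gi in slots:
            ev = slots[gi]
            pad_l = _random_seq(rng, 60)
            born_seq, b_exons, b_cds = _make_orf(rng, ev.orf_codons, ev.intron_len)
            proto = _degrade_to_noncoding(born_seq, rng)
            pad_r = _random_seq(rng, 60)
            pieces.append(pad_l)
            cursor += len(pad_l)
            tracked[ev.locus_id] = (region, cursor, cursor + len(proto))
            payload[ev.locus_id] = {
                "born_seq": born_seq,
                "exons": b_exons,
                "cds": b_cds,
            }
            pieces.append(proto)
            cursor += len(proto)
            pieces.append(pad_r)
            cursor += len(pad_r)
    tail = _random_seq(
        rng, int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
    )
    pieces.append(tail)
    genome = AnnotatedGenome(
        species_id="ancestor", sequences={region: "".join(pieces)}, genes=genes
    )
    lineage = _lineage_from_genome(genome)
    lineage.tracked = tracked
    return genome, {"lineage": lineage, "payload": payload}


def _apply_de_novo(lineage: _Lineage, ev: EventSpec, payload: dict) -> None:
    region, start, end = lineage.tracked[ev.locus_id]
    born = payload["born_seq"]
    seq = lineage.seqs[region]
    # the progenitor locus may have drifted in length; replace it wholesale
    delta = len(born) - (end - start)
    lineage.seqs[region] = seq[:start] + born + seq[end:]
    if delta:
        _lift_features(lineage, region, end, delta)
    lineage.tracked[ev.locus_id] = (region, start, start + len(born))
    lineage.genes.append(
        GeneModel(
            gene_id=ev.locus_id,
            seq_region=region,
            strand="+",
            exons=[Interval(iv.start + start, iv.end + start) for iv in payload["exons"]],
            cds_segments=[
                Interval(iv.start + start, iv.end + start) for iv in payload["cds"]
            ],
            biotype="protein_coding",
        )
    )
    lineage.genes.sort(key=lambda g: (g.seq_region, g.span.start))


def _intergenic_gaps(lineage: _Lineage, region: str, min_len: int) -> list[tuple[int, int]]:
    spans = sorted(
        (g.span.start, g.span.end)
        for g in lineage.genes
        if g.seq_region == region
    )
    tracked = sorted(
        (s, e) for reg, s, e in lineage.tracked.values() if reg == region
    )
    occupied = sorted(spans + tracked)
    gaps = []
    prev = 0
    for s, e in occupied:
        if s - prev >= min_len:
            gaps.append((prev, s))
        prev = max(prev, e)
    L = len(lineage.seqs[region])
    if L - prev >= min_len:
        gaps.append((prev, L))
    return gaps


def _apply_duplication(
    lineage: _Lineage, ev: EventSpec, rng: np.random.Generator
) -> None:
    candidates = [
        g for g in lineage.genes
        if g.biotype == "protein_coding" and g.gene_id not in lineage.multipliers
    ]
    if ev.source_gene:
        source = next(g for g in lineage.genes if g.gene_id == ev.source_gene)
    else:
        source = candidates[int(rng.integers(0, len(candidates)))]
        ev.source_gene = source.gene_id
    region = source.seq_region
    span = source.span
    gene_seq = lineage.seqs[region][span.start : span.end]
    # capture structure relative to the span BEFORE the insertion lifts
    # the source gene's own coordinates
    rel_exons = [Interval(iv.start - span.start, iv.end - span.start) for iv in source.exons]
    rel_cds = [
        Interval(iv.start - span.start, iv.end - span.start)
        for iv in source.cds_segments
    ]
    # insertion makes its own room; the point just needs clear flanks
    gaps = _intergenic_gaps(lineage, region, 60)
    if not gaps:
        raise SimulationError(f"no intergenic gap for duplication {ev.locus_id}")
    gs, ge = gaps[int(rng.integers(0, len(gaps)))]
    pos = (gs + ge) // 2
    seq = lineage.seqs[region]
    lineage.seqs[region] = seq[:pos] + gene_seq + seq[pos:]
    _lift_features(lineage, region, pos, len(gene_seq))
    copy_gene = GeneModel(
        gene_id=ev.locus_id,
        seq_region=region,
        strand=source.strand,
        exons=[Interval(iv.start + pos, iv.end + pos) for iv in rel_exons],
        cds_segments=[Interval(iv.start + pos, iv.end + pos) for iv in rel_cds],
        biotype="protein_coding",
    )
    lineage.genes.append(copy_gene)
    lineage.genes.sort(key=lambda g: (g.seq_region, g.span.start))
    lineage.multipliers[ev.locus_id] = ev.rate_multiplier


def _apply_pseudogenization(
    lineage: _Lineage, ev: EventSpec, rng: np.random.Generator
) -> None:
    candidates = [
        g for g in lineage.genes
        if g.biotype == "protein_coding" and g.gene_id not in lineage.multipliers
    ]
    if ev.source_gene:
        gene = next(g for g in lineage.genes if g.gene_id == ev.source_gene)
    else:
        gene = candidates[int(rng.integers(0, len(candidates)))]
        ev.source_gene = gene.gene_id
    # premature stop ~25% into the CDS
    segs = gene.cds_segments if gene.strand == "+" else gene.cds_segments[::-1]
    flat: list[int] = []
    for seg in segs:
        r = range(seg.start, seg.end)
        flat.extend(r if gene.strand == "+" else reversed(r))
    codon_i = max(1, len(flat) // 3 // 4)
    stop = "TAA"
    seq = list(lineage.seqs[gene.seq_region])
    for k, p in enumerate(flat[3 * codon_i : 3 * codon_i + 3]):
        base = stop[k]
        seq[p] = base if gene.strand == "+" else reverse_complement(base)
    lineage.seqs[gene.seq_region] = "".join(seq)
    gene.biotype = "pseudogene"
    lineage.tracked.setdefault(
        ev.locus_id, (gene.seq_region, gene.span.start, gene.span.end)
    )


def _apply_gene_loss(
    lineage: _Lineage, ev: EventSpec, rng: np.random.Generator
) -> None:
    if ev.source_gene:
        gene = next(g for g in lineage.genes if g.gene_id == ev.source_gene)
    else:
        pc = [g for g in lineage.genes if g.biotype == "protein_coding"]
        gene = pc[int(rng.integers(0, len(pc)))]
        ev.source_gene = gene.gene_id
    span = gene.span
    region = gene.seq_region
    lineage.genes = [g for g in lineage.genes if g.gene_id != gene.gene_id]
    seq = lineage.seqs[region]
    lineage.seqs[region] = seq[: span.start] + seq[span.end :]
    _lift_features(lineage, region, span.start, -(len(span)))


_EVENT_APPLIERS = {
    "duplication_divergence": _apply_duplication,
    "pseudogenization": _apply_pseudogenization,
    "gene_loss": _apply_gene_loss,
}


# ---------------------------------------------------------------------------
# Clade simulation
# ---------------------------------------------------------------------------


def simulate_clade(
    tree: Optional[SpeciesTree] = None,
    ancestral_genome_params: Optional[AncestralGenomeParams] = None,
    events: Iterable[EventSpec] = (),
    seed: int | np.random.Generator = 0,
    indel_params: Optional[IndelParams] = None,
) -> tuple[dict[str, AnnotatedGenome], pd.DataFrame]:
    """Simulate a clade of annotated genomes with planted events.

    Returns a map species_id → AnnotatedGenome for every leaf, plus the
    truth table: one row per (locus, species) with the event type, whether
    the locus is annotated as a gene in that species, and its genomic
    coordinates. Coordinates in the truth table match the emitted
    annotations exactly (checked by :func:`verify_truth`).
    """
    tree = tree or default_species_tree()
    params = ancestral_genome_params or AncestralGenomeParams()
    ip = indel_params or IndelParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = list(events)
    node_names = {n.name for n in tree._walk()}
    for ev in events:
        if ev.branch not in node_names:
            raise SimulationError(f"event branch {ev.branch!r} not in tree")
    de_novo = [e for e in events if e.event_type == "de_novo_birth"]
    _, state = _build_ancestor(params, de_novo, rng)
    root_lineage: _Lineage = state["lineage"]
    payloads: dict[str, dict] = state["payload"]

    events_by_branch: dict[str, list[EventSpec]] = {}
    for ev in events:
        events_by_branch.setdefault(ev.branch, []).append(ev)

    genomes: dict[str, AnnotatedGenome] = {}
    bearing: dict[str, set[str]] = {ev.locus_id: set() for ev in events}

    def mark_bearing(node: TreeNode, locus: str) -> None:
        for leaf in node.leaves():
            bearing[locus].add(leaf.name)

    def recurse(node: TreeNode, lineage: _Lineage) -> None:
        for child in node.children:
            child_lineage = copy.deepcopy(lineage)
            for ev in events_by_branch.get(child.name, []):
                if ev.event_type == "de_novo_birth":
                    _apply_de_novo(child_lineage, ev, payloads[ev.locus_id])
                else:
                    _EVENT_APPLIERS[ev.event_type](child_lineage, ev, rng)
                mark_bearing(child, ev.locus_id)
            _evolve_lineage(child_lineage, child.length, ip, rng)
            if child.is_leaf:
                genomes[child.name] = genome_from_lineage(child.name, child_lineage)
                leaf_tracked[child.name] = dict(child_lineage.tracked)
            else:
                recurse(child, child_lineage)

    leaf_tracked: dict[str, dict[str, tuple[str, int, int]]] = {}
    for ev in events_by_branch.get(tree.root.name, []):
        if ev.event_type == "de_novo_birth":
            _apply_de_novo(root_lineage, ev, payloads[ev.locus_id])
        else:
            _EVENT_APPLIERS[ev.event_type](root_lineage, ev, rng)
        mark_bearing(tree.root, ev.locus_id)
    recurse(tree.root, root_lineage)

    rows = []
    for ev in events:
        for species in tree.leaf_names:
            genome = genomes[species]
            annotated = any(
                g.gene_id == ev.locus_id and g.biotype == "protein_coding"
                for g in genome.genes
            )
            coords: Optional[tuple[str, int, int]] = None
            if ev.locus_id in {g.gene_id for g in genome.genes}:
                g = genome.gene(ev.locus_id)
                coords = (g.seq_region, g.span.start, g.span.end)
            elif ev.locus_id in leaf_tracked.get(species, {}):
                coords = leaf_tracked[species][ev.locus_id]
            rows.append(
                {
                    "locus_id": ev.locus_id,
                    "event": ev.event_type,
                    "species": species,
                    "bearing": species in bearing[ev.locus_id],
                    "annotated": annotated,
                    "seq_region": coords[0] if coords else "",
                    "start": coords[1] if coords else -1,
                    "end": coords[2] if coords else -1,
                    "source_gene": ev.source_gene or "",
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "event", "species", "bearing", "annotated",
            "seq_region", "start", "end", "source_gene",
        ],
    )
    verify_truth(genomes, truth)
    return genomes, truth


def verify_truth(
    genomes: dict[str, AnnotatedGenome], truth: pd.DataFrame
) -> None:
    """Programmatic consistency check after every simulation: truth-table
    coordinates match emitted annotations, and every annotated CDS translates
    without internal stops (planted pseudogenes excepted)."""
    for _, row in truth.iterrows():
        if not row["annotated"]:
            continue
        genome = genomes[row["species"]]
        gene = genome.gene(row["locus_id"])
        if (gene.seq_region, gene.span.start, gene.span.end) != (
            row["seq_region"], row["start"], row["end"],
        ):
            raise SimulationError(
                f"truth/annotation mismatch for {row['locus_id']} in {row['species']}"
            )
    for species, genome in genomes.items():
        for gene in genome.protein_coding_genes:
            prot = translate(extract_feature_sequence(genome, gene, "cds"))
            if "*" in prot[:-1]:
                raise SimulationError(
                    f"internal stop in {species}/{gene.gene_id} after simulation"
                )


def default_study_events() -> list[EventSpec]:
    """The default planted-event panel mirroring the study design: one de novo
    birth on the simulans–sechellia stem, one rapidly diverging duplicate on
    the same stem, one pseudogenization in the yakuba-like outgroup."""
    return [
        EventSpec("dn1", "de_novo_birth", branch="simsec", orf_codons=120, intron_len=52),
        EventSpec("dup1", "duplication_divergence", branch="simsec", rate_multiplier=15.0),
        EventSpec("ps1", "pseudogenization", branch="yak"),
    ]
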