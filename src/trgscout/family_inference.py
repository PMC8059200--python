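"""Cross-species homologous gene families and clade-restricted candidate
selection.

Families are built from all-vs-all protein comparisons: a pair is accepted
as homologous when a significant local alignment exists and the alignment
covers at least 61% of the shorter protein (the length tolerance ratio;
pairs strictly below 61% are rejected). Accepted pairs form a graph whose
connected components are the families. Candidate taxonomically restricted
gene families (TRGFs) are the families with members in at least two focal
species and none outside the focal clade; candidates are then screened
against outgroup proteins, a family being removed only when *every* member
has at least one qualifying outside hit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .genome_io import AnnotatedGenome, gene_protein
from .similarity_search import (
    ScoringScheme,
    default_protein_scheme,
    evalue,
    search_protein,
    smith_waterman,
    smith_waterman_score,
)

Member = tuple[str, str]  # (species_id, gene_id)


@dataclass(frozen=True)
class HomologyFamily:
    family_id: str
    members: frozenset[Member]
    provenance: tuple[tuple[Member, Member], ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family must be non-empty")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.members)


@dataclass(frozen=True)
class CladePartition:
    """Focal species vs outgroups. ``ingroup_outgroups`` are the closest
    outgroups (used for ORF-conservation tests); ``distant_outgroups`` are
    ordered by increasing divergence."""

    focal_species: frozenset[str]
    ingroup_outgroups: frozenset[str]
    distant_outgroups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.focal_species) < 2:
            raise ValueError("focal clade needs at least 2 species")
        overlap = self.focal_species & (
            self.ingroup_outgroups | set(self.distant_outgroups)
        )
        if overlap or set(self.distant_outgroups) & self.ingroup_outgroups:
            raise ValueError("partition sets must be disjoint")

    @property
    def outgroups(self) -> frozenset[str]:
        return self.ingroup_outgroups | set(self.distant_outgroups)


def default_partition() -> CladePartition:
    return CladePartition(
        focal_species=frozenset({"sim", "sec", "mel"}),
        ingroup_outgroups=frozenset({"yak", "ere"}),
    )


def proteome_of(genome: AnnotatedGenome) -> dict[str, str]:
    """gene_id -> protein for every protein-coding gene (pseudogenes and
    ncRNAs are not part of the searchable protein space)."""
    out = {}
    for gene in genome.protein_coding_genes:
        prot = gene_protein(genome, gene)
        if prot:
            out[gene.gene_id] = prot
    return out


def pairwise_homologous(
    protein_a: str,
    protein_b: str,
    scheme: Optional[ScoringScheme] = None,
    length_tolerance: float = 0.61,
    max_e: float = 1e-3,
    search_space: Optional[int] = None,
) -> bool:
    """Homology test for one protein pair.

    True iff a significant local alignment exists (e-value ≤ ``max_e``) AND
    alignment_length / min(len_a, len_b) ≥ ``length_tolerance``. The boundary
    is inclusive: exactly 61% passes. ``search_space`` is the subject-side
    residue count used for significance; all-vs-all callers pass the total
    database size (the search-against-a-database semantics), and it defaults
    to len(protein_b) for an isolated pair.
    """
    if not protein_a or not protein_b:
        raise ValueError("proteins must be non-empty")
    scheme = scheme or default_protein_scheme()
    score = smith_waterman_score(protein_a, protein_b, scheme)
    if score <= 0:
        return False
    n = search_space if search_space is not None else len(protein_b)
    if evalue(score, len(protein_a), n, scheme) > max_e:
        return False
    # only significant pairs pay for the full traceback
    aln = smith_waterman(protein_a, protein_b, scheme)
    ratio = aln.length / min(len(protein_a), len(protein_b))
    return ratio >= length_tolerance


def _family_id(members: Iterable[Member]) -> str:
    canon = ";".join(f"{s}:{g}" for s, g in sorted(members))
    return "fam_" + hashlib.sha1(canon.encode()).hexdigest()[:10]


def _shared_kmers(a: str, b_words: set[str], k: int) -> bool:
    return any(a[i : i + k] in b_words for i in range(len(a) - k + 1))


def build_families(
    proteomes: Mapping[str, Mapping[str, str]],
    scheme: Optional[ScoringScheme] = None,
    length_tolerance: float = 0.61,
    max_e: float = 1e-3,
) -> list[HomologyFamily]:
    """All-vs-all accepted pairs → connected components → families.

    ``proteomes`` maps species_id -> {gene_id: protein}. Genes with no
    accepted partner become singleton families. Family ids are deterministic
    hashes of the sorted member list. An exact k-mer prescreen skips pairs
    that share no seed word (such pairs cannot reach a significant score).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    scheme = scheme or default_protein_scheme()
    k = scheme.seed_k
    entries: list[tuple[Member, str]] = [
        ((sp, gid), prot)
        for sp in sorted(proteomes)
        for gid, prot in sorted(proteomes[sp].items())
    ]
    words = [
        {p[i : i + k] for i in range(len(p) - k + 1)} for _, p in entries
    ]
    graph = nx.Graph()
    graph.add_nodes_from(m for m, _ in entries)
    db_size = sum(len(p) for _, p in entries)
    edges = []
    for i in range(len(entries)):
        (mi, pi) = entries[i]
        for j in range(i + 1, len(entries)):
            (mj, pj) = entries[j]
            if mi[0] == mj[0]:
                continue  # within-species paralogy does not link families here
            if not (words[i] & words[j]):
                continue
            if pairwise_homologous(
                pi, pj, scheme, length_tolerance, max_e, search_space=db_size
            ):
                edges.append((mi, mj))
    graph.add_edges_from(edges)
    families = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        prov = tuple(
            sorted((a, b) if a <= b else (b, a) for a, b in edges
                   if a in members and b in members)
        )
        families.append(
            HomologyFamily(
                family_id=_family_id(members), members=members, provenance=prov
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def select_trgf_candidates(
    families: Sequence[HomologyFamily], partition: CladePartition
) -> list[HomologyFamily]:
    """Families with members in ≥ 2 *distinct* focal species and no members
    outside the focal clade. Singleton-species families are excluded — without
    cross-species conservation there is insufficient evidence of function."""
    out = []
    for fam in families:
        focal = fam.species & partition.focal_species
        outside = fam.species - partition.focal_species
        if len(focal) >= 2 and not outside:
            out.append(fam)
    return sorted(out, key=lambda f: f.family_id)


def protein_screen(
    candidates: Sequence[HomologyFamily],
    outgroup_proteins: Mapping[str, Mapping[str, str]],
    member_proteins: Mapping[Member, str],
    scheme: Optional[ScoringScheme] = None,
    max_e: float = 1e-3,
    min_cov: float = 0.5,
) -> tuple[list[HomologyFamily], dict[str, str]]:
    """Screen candidates against proteins outside the focal clade.

    A family is removed iff EVERY member protein has at least one hit with
    e-value ≤ ``max_e`` covering ≥ ``min_cov`` of the query against the
    outgroup protein collections; otherwise it is retained. Returns the
    surviving candidates and a map family_id → removal reason.
    """
    scheme = scheme or default_protein_scheme()
    surviving, removed = [], {}
    for fam in candidates:
        members_hit = []
        for member in sorted(fam.members):
            query = member_proteins[member]
            hits = search_protein(
                query, dict(outgroup_proteins), scheme,
                query_id=f"{member[0]}:{member[1]}", max_e=max_e, min_cov=min_cov,
            )
            members_hit.append(bool(hits))
        if members_hit and all(members_hit):
            removed[fam.family_id] = (
                "every member has a qualifying protein hit outside the clade "
                "(diverged homolog; earlier origin)"
            )
        else:
            surviving.append(fam)
    return surviving, removed


def write_family_table(families: Sequence[HomologyFamily], path) -> None:
    """Flat TSV: family_id, species, gene_id (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("family_id\tspecies\tgene_id\n")
        for fam in sorted(families, key=lambda f: f.family_id):
            for species, gene_id in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{species}\t{gene_id}\n")
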