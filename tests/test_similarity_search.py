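"""Local alignment, significance and hit post-processing.

The brute-force oracle enumerates all local alignment paths (with affine
gap costs) by suffix-max recursion over (i, j, gap-state); it is written
against the scoring definition directly and shares no code with the
production engine.
"""

import math
from functools import lru_cache

import numpy as np
import pytest

from trgscout.genome_io import AnnotatedGenome, Interval, reverse_complement
from trgscout.similarity_search import (
    RegionHit,
    ScoringScheme,
    amalgamate_hits,
    cap_hits,
    default_nucleotide_scheme,
    default_protein_scheme,
    evalue,
    intragenomic_duplicates,
    search,
    search_protein,
    smith_waterman,
)


def brute_force_local_score(a, b, match=1.0, mismatch=-2.0, gap_open=5.0, gap_extend=2.0):
    """Best local alignment score by exhaustive path enumeration (cached).

    A gap of length L costs gap_open + gap_extend*L. An alignment may start
    and stop anywhere; the empty alignment scores 0.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def best_from(i, j, state):
        # best score of any alignment continuation from (i, j); stopping
        # here is always allowed (score 0)
        res = 0.0
        if i < n and j < m:
            sub = match if a[i] == b[j] else mismatch
            res = max(res, sub + best_from(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend + (gap_open if state != "A" else 0.0)
            res = max(res, -cost + best_from(i + 1, j, "A"))
        if j < m:
            cost = gap_extend + (gap_open if state != "B" else 0.0)
            res = max(res, -cost + best_from(i, j + 1, "B"))
        return res

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, best_from(i, j, "start"))
    best_from.cache_clear()
    return best


class TestSmithWaterman:
    def test_self_alignment(self, nt_scheme):
        aln = smith_waterman("ACGT", "ACGT", nt_scheme)
        assert aln.score == 4.0
        assert aln.a_interval == Interval(0, 4)
        assert aln.b_interval == Interval(0, 4)

    def test_no_positive_cell_gives_empty_alignment(self, nt_scheme):
        aln = smith_waterman("AAAA", "TTTT", nt_scheme)
        assert aln.score == 0.0
        assert aln.length == 0

    def test_alphabet_mismatch_rejected(self, nt_scheme):
        with pytest.raises(ValueError):
            smith_waterman("ACGT", "ACGU", nt_scheme)

    def test_matches_brute_force_on_short_random_pairs(self, nt_scheme):
        rng = np.random.default_rng(99)
        for _ in range(200):
            la, lb = rng.integers(1, 9, 2)
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, la))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, lb))
            got = smith_waterman(a, b, nt_scheme).score
            want = brute_force_local_score(a, b)
            assert got == want, (a, b)


class TestEvalue:
    def test_direct_formula(self):
        scheme = ScoringScheme(
            "nucleotide", default_nucleotide_scheme().matrix,
            5, 2, lambda_=0.267, k_param=0.041, seed_k=11,
        )
        expected = 0.041 * 100 * 100 * math.exp(-0.267 * 40)
        assert evalue(40, 100, 100, scheme) == pytest.approx(expected)

    def test_monotone_decreasing_in_score(self, nt_scheme):
        es = [evalue(s, 500, 500, nt_scheme) for s in (10, 20, 40, 80)]
        assert es == sorted(es, reverse=True)

    def test_linear_in_search_space(self, nt_scheme):
        assert evalue(30, 100, 200, nt_scheme) == pytest.approx(
            2 * evalue(30, 100, 100, nt_scheme)
        )


def _genome_with(seq, species="subj"):
    return AnnotatedGenome(species_id=species, sequences={"chr1": seq}, genes=[])


class TestSearch:
    def test_verbatim_query_found_plus_strand(self, nt_scheme, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        genome = _genome_with(flank + insert + flank[::-1])
        hits = search(insert, [genome], nt_scheme)
        assert any(
            h.strand == "+" and h.query_coverage == 1.0 and
            h.interval == Interval(300, 360)
            for h in hits
        )

    def test_reverse_complement_query_found_minus_strand(self, nt_scheme, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        genome = _genome_with(flank + insert + flank[::-1])
        hits = search(reverse_complement(insert), [genome], nt_scheme)
        assert any(
            h.strand == "-" and h.interval == Interval(300, 360) for h in hits
        )

    def test_empty_database_gives_empty_result(self, nt_scheme):
        assert search("ACGTACGTACGTACGT", [], nt_scheme) == []

    def test_filters_are_monotone(self, nt_scheme, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        genome = _genome_with(flank + insert + flank[::-1])
        loose = search(insert, [genome], nt_scheme, max_e=1.0, min_cov=0.0)
        tight_e = search(insert, [genome], nt_scheme, max_e=1e-6, min_cov=0.0)
        tight_cov = search(insert, [genome], nt_scheme, max_e=1.0, min_cov=0.9)
        keys = lambda hits: {(h.seq_region, h.interval, h.strand) for h in hits}
        assert keys(tight_e) <= keys(loose)
        assert keys(tight_cov) <= keys(loose)


def _hit(qs, qe, ss, se, qlen=100, e=1e-5, species="s1", region="chr1",
         strand="+", score=50.0, query="q"):
    return RegionHit(
        query_id=query, query_interval=Interval(qs, qe), query_length=qlen,
        subject_genome=species, seq_region=region, interval=Interval(ss, se),
        strand=strand, score=score, e_value=e,
    )


class TestAmalgamate:
    def test_overlapping_merged_to_union(self):
        merged = amalgamate_hits([_hit(0, 50, 100, 200), _hit(40, 90, 150, 250)])
        assert len(merged) == 1
        assert merged[0].interval == Interval(100, 250)
        assert merged[0].query_interval == Interval(0, 90)

    def test_disjoint_untouched(self):
        merged = amalgamate_hits([_hit(0, 50, 100, 200), _hit(0, 50, 300, 400)])
        assert len(merged) == 2

    def test_different_strands_not_merged(self):
        merged = amalgamate_hits(
            [_hit(0, 50, 100, 200), _hit(0, 50, 150, 250, strand="-")]
        )
        assert len(merged) == 2

    def test_idempotent_and_order_invariant(self):
        hits = [
            _hit(0, 50, 100, 200), _hit(40, 90, 150, 250), _hit(0, 30, 400, 500),
        ]
        once = amalgamate_hits(hits)
        assert amalgamate_hits(once) == once
        assert amalgamate_hits(hits[::-1]) == once

    def test_merged_hit_keeps_min_evalue(self):
        merged = amalgamate_hits(
            [_hit(0, 50, 100, 200, e=1e-3), _hit(10, 60, 150, 250, e=1e-9)]
        )
        assert merged[0].e_value == 1e-9


class TestCapHits:
    def _many(self, n, n_species=5):
        return [
            _hit(0, 50, i, i + 50, e=1e-6 + i * 1e-9, species=f"sp{i % n_species}")
            for i in range(n)
        ]

    def test_exactly_at_limit_untouched(self):
        hits = self._many(1000)
        assert cap_hits(hits) == hits

    def test_over_limit_keeps_five_best_per_species(self):
        capped = cap_hits(self._many(1001))
        assert len(capped) == 25
        by_sp = {}
        for h in capped:
            by_sp.setdefault(h.subject_genome, []).append(h)
        assert all(len(v) == 5 for v in by_sp.values())
        # kept hits are the smallest e-values per species
        for sp, kept in by_sp.items():
            assert max(h.e_value for h in kept) <= 1e-6 + 30 * 1e-9

    def test_species_with_fewer_hits_keeps_all(self):
        hits = self._many(1001) + [_hit(0, 50, 0, 50, species="rare")]
        capped = cap_hits(hits)
        assert sum(1 for h in capped if h.subject_genome == "rare") == 1


class TestIntragenomicDuplicates:
    def test_unique_region_has_no_duplicates(self, nt_scheme, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        genome = _genome_with(seq)
        assert intragenomic_duplicates(("chr1", Interval(500, 700)), genome, nt_scheme) == []

    def test_planted_tandem_copy_found_once(self, nt_scheme, rng):
        block = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        genome = _genome_with(filler + block + filler[::-1] + block + filler)
        region = ("chr1", Interval(800, 1000))  # first copy
        hits = intragenomic_duplicates(region, genome, nt_scheme)
        non_self = [h for h in hits if not h.interval.overlaps(Interval(800, 1000))]
        assert len(non_self) >= 1
        assert any(h.interval == Interval(1800, 2000) for h in non_self)


class TestStrandInvariance:
    def test_hits_reflect_under_genome_reverse_complement(self, nt_scheme, rng):
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = flank + insert + flank[::-1]
        L = len(seq)
        fwd = search(insert, [_genome_with(seq)], nt_scheme)
        rev = search(insert, [_genome_with(reverse_complement(seq))], nt_scheme)
        fwd_keys = {(h.interval.start, h.interval.end, h.strand) for h in fwd}
        rev_keys = {
            (L - h.interval.end, L - h.interval.start,
             "+" if h.strand == "-" else "-")
            for h in rev
        }
        assert fwd_keys == rev_keys
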