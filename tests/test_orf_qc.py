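import re

import numpy as np
import pytest

from trgscout.family_inference import HomologyFamily
from trgscout.genome_io import AnnotatedGenome, GeneModel, Interval
from trgscout.orf_qc import (
    OrfCall,
    annotation_consistency,
    find_orfs,
    outgroup_orf_conservation,
    splice_signal_check,
)
from trgscout.region_homology import AlignmentRow, RegionAlignment


def naive_orf_scan(seq, min_codons):
    """Regex-style independent scanner: maximal ATG..stop runs per frame."""
    found = []
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                for j in range(i, len(codons)):
                    if codons[j] in ("TAA", "TAG", "TGA"):
                        orf = codons[i : j + 1]
                        if len(orf) >= min_codons and not any("N" in c for c in orf):
                            found.append((frame, frame + 3 * i, frame + 3 * (j + 1)))
                        i = j  # next start searched after this stop
                        break
                else:
                    break
            i += 1
    return sorted(found, key=lambda t: (t[1], t[0]))


class TestFindOrfs:
    def test_minimal_orf(self):
        calls = find_orfs("ATGAAATAA", min_orf_codons=2)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.length_codons, c.frame) == (0, 9, 3, 0)

    def test_start_without_stop_not_called(self):
        assert find_orfs("ATGAA", min_orf_codons=1) == []

    def test_orfs_with_n_skipped(self):
        assert find_orfs("ATGANATAA", min_orf_codons=1) == []

    def test_matches_naive_scanner_on_random_sequence(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        got = [(c.frame, c.start, c.end) for c in find_orfs(seq, min_orf_codons=10)]
        assert got == naive_orf_scan(seq, 10)
        for c in find_orfs(seq, min_orf_codons=10):
            assert seq[c.start : c.start + 3] == "ATG"
            assert seq[c.end - 3 : c.end] in ("TAA", "TAG", "TGA")
            assert (c.end - c.start) // 3 == c.length_codons
            inner = [seq[i : i + 3] for i in range(c.start + 3, c.end - 3, 3)]
            assert not any(x in ("TAA", "TAG", "TGA") for x in inner)


def _gapless_alignment(rows):
    out = []
    for sp, g in rows:
        ung = g.replace("-", "")
        coord, pos = [], 0
        for ch in g:
            if ch == "-":
                coord.append(None)
            else:
                coord.append(pos)
                pos += 1
        out.append(
            AlignmentRow(
                species_id=sp, seq_region="chr1",
                interval=Interval(0, len(ung)), strand="+",
                gapped=g, coord_map=coord,
            )
        )
    return RegionAlignment(rows=out)


class TestOutgroupOrfConservation:
    def _candidate(self, n_codons=30):
        # candidate ORF of n_codons incl. stop, flanked by 30 nt each side
        body = "ATG" + "GCT" * (n_codons - 2) + "TAA"
        flank = "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCC"
        return flank + body + flank, Interval(30, 30 + len(body))

    def test_identical_outgroup_row_flags_full_coverage(self):
        seq, orf_iv = self._candidate()
        aln = _gapless_alignment([("cand", seq), ("out1", seq)])
        flag, ev = outgroup_orf_conservation(
            aln, "cand", orf_iv, ["out1"], min_orf_codons=5
        )
        assert flag and ev["out1"] == 1.0

    def test_coverage_boundary_at_half(self):
        seq, orf_iv = self._candidate(n_codons=30)  # 90 nt ORF
        # outgroup ORF covering exactly half: stop planted after codon 15
        half = seq[:30] + "ATG" + "GCT" * 13 + "TAA" + seq[30 + 45 :]
        assert len(half) == len(seq)
        aln = _gapless_alignment([("cand", seq), ("out1", half)])
        flag_at, ev = outgroup_orf_conservation(
            aln, "cand", orf_iv, ["out1"], threshold=0.5, min_orf_codons=5
        )
        assert ev["out1"] == pytest.approx(0.5)
        assert flag_at  # boundary inclusive
        flag_above, _ = outgroup_orf_conservation(
            aln, "cand", orf_iv, ["out1"], threshold=0.501, min_orf_codons=5
        )
        assert not flag_above

    def test_disrupted_outgroup_not_flagged(self):
        seq, orf_iv = self._candidate()
        # outgroup: no ATG and stops sprinkled
        disrupted = seq.replace("ATG", "ATA").replace("GCTGCTGCT", "GCTTAAGCT")
        aln = _gapless_alignment([("cand", seq), ("out1", disrupted)])
        flag, _ = outgroup_orf_conservation(
            aln, "cand", orf_iv, ["out1"], min_orf_codons=5
        )
        assert not flag

    def test_monotone_in_threshold(self):
        seq, orf_iv = self._candidate()
        aln = _gapless_alignment([("cand", seq), ("out1", seq)])
        flags = [
            outgroup_orf_conservation(
                aln, "cand", orf_iv, ["out1"], threshold=t, min_orf_codons=5
            )[0]
            for t in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(a or not b for a, b in zip(flags, flags[1:]))

    def test_candidate_covers_itself_fully(self):
        seq, orf_iv = self._candidate()
        aln = _gapless_alignment([("cand", seq), ("out1", seq)])
        _, ev = outgroup_orf_conservation(
            aln, "cand", orf_iv, ["cand"], min_orf_codons=5
        )
        assert ev["cand"] == 1.0


class TestSpliceSignals:
    def _one_gene_genome(self, seq, exons, strand="+"):
        gene = GeneModel(
            gene_id="g", seq_region="chr1", strand=strand,
            exons=exons, cds_segments=exons,
        )
        return AnnotatedGenome("t", {"chr1": seq}, [gene]), gene

    def test_canonical_intron(self):
        seq = "ATGAAA" + "GTTTAG" + "TGCTAA"
        genome, gene = self._one_gene_genome(
            seq, [Interval(0, 6), Interval(12, 18)]
        )
        assert splice_signal_check(genome, gene) == [True]

    def test_noncanonical_intron(self):
        seq = "ATGAAA" + "GCTTAG" + "TGCTAA"
        genome, gene = self._one_gene_genome(
            seq, [Interval(0, 6), Interval(12, 18)]
        )
        assert splice_signal_check(genome, gene) == [False]

    def test_minus_strand_canonical(self):
        # minus-strand gene: plus-strand genomic intron reads CT..AC
        from trgscout.genome_io import reverse_complement

        plus_exon2 = "TTAGCA"  # rc = TGCTAA
        intron_rc = "GTTTAG"
        plus_intron = reverse_complement(intron_rc)  # CTAAAC
        plus_exon1 = "TTTCAT"  # rc = ATGAAA
        seq = plus_exon2 + plus_intron + plus_exon1
        genome, gene = self._one_gene_genome(
            seq, [Interval(0, 6), Interval(12, 18)], strand="-"
        )
        assert splice_signal_check(genome, gene) == [True]

    def test_intronless_gene_rejected(self):
        seq = "ATGAAATAA"
        genome, gene = self._one_gene_genome(seq, [Interval(0, 9)])
        with pytest.raises(ValueError):
            splice_signal_check(genome, gene)


class TestAnnotationConsistency:
    def _two_species(self, mutate_sec=None):
        seq = "CCCCC" + "ATGAAA" + "GTTTAG" + "TGCTAA" + "CCCCC"
        exons = [Interval(5, 11), Interval(17, 23)]

        def build(species, seq):
            gene = GeneModel(
                gene_id="g1", seq_region="chr1", strand="+",
                exons=list(exons), cds_segments=list(exons),
            )
            return AnnotatedGenome(species, {"chr1": seq}, [gene])

        sec_seq = mutate_sec(seq) if mutate_sec else seq
        genomes = {"sim": build("sim", seq), "sec": build("sec", sec_seq)}
        fam = HomologyFamily(
            family_id="f1", members=frozenset({("sim", "g1"), ("sec", "g1")})
        )
        return fam, genomes

    def test_clean_family_passes(self):
        fam, genomes = self._two_species()
        assert annotation_consistency(fam, genomes).passed

    def test_missing_start_flagged(self):
        fam, genomes = self._two_species(
            mutate_sec=lambda s: s.replace("ATGAAA", "ATAAAA")
        )
        report = annotation_consistency(fam, genomes)
        assert not report.passed and report.missing_start == ["sec"]

    def test_missing_stop_flagged(self):
        fam, genomes = self._two_species(
            mutate_sec=lambda s: s.replace("TGCTAA", "TGCTAC")
        )
        report = annotation_consistency(fam, genomes)
        assert not report.passed and report.missing_stop == ["sec"]

    def test_noncanonical_splice_flagged(self):
        fam, genomes = self._two_species(
            mutate_sec=lambda s: s.replace("GTTTAG", "GCTTAG")
        )
        report = annotation_consistency(fam, genomes)
        assert not report.passed and report.noncanonical_splice == ["sec"]

    def test_single_annotated_species_fails_conservation_requirement(self):
        fam, genomes = self._two_species()
        genomes["sec"].genes[0].biotype = "ncRNA"
        report = annotation_consistency(fam, genomes)
        assert not report.passed and report.too_few_annotated

    def test_pass_invariant_to_species_order(self):
        fam, genomes = self._two_species()
        rev = dict(reversed(list(genomes.items())))
        assert (
            annotation_consistency(fam, genomes).passed
            == annotation_consistency(fam, rev).passed
        )

    def test_misaligned_starts_flagged_with_alignment(self):
        fam, genomes = self._two_species()
        # sec row shifted 30 columns relative to sim in the alignment
        sim_seq = genomes["sim"].sequences["chr1"]
        aln = _gapless_alignment(
            [("sim", sim_seq + "-" * 30), ("sec", "-" * 30 + sim_seq)]
        )
        report = annotation_consistency(fam, genomes, aln, column_slack=0)
        assert report.inconsistent_start and report.inconsistent_stop
        # generous slack accepts the same offset
        report2 = annotation_consistency(fam, genomes, aln, column_slack=40)
        assert report2.passed
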