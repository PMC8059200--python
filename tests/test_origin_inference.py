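"""Origin evidence: intron mod-3 logic, conserved-stop frame analysis
(verified against a naive per-row six-frame scanner), start-codon checks and
the classification decision table.
"""

import pytest

from trgscout.genome_io import Interval
from trgscout.origin_inference import (
    FrameConvention,
    OriginEvidence,
    classify_origin,
    conserved_stop_frames,
    distant_outgroup_start_check,
    intron_mod3_test,
    synteny_context,
)
from trgscout.region_homology import AlignmentRow, RegionAlignment

STOPS = ("TAA", "TAG", "TGA")


def make_alignment(rows):
    out = []
    for sp, gapped in rows:
        ung = gapped.replace("-", "")
        coord, pos = [], 0
        for ch in gapped:
            if ch == "-":
                coord.append(None)
            else:
                coord.append(pos)
                pos += 1
        out.append(
            AlignmentRow(
                species_id=sp, seq_region="chr1",
                interval=Interval(0, len(ung)), strand="+",
                gapped=gapped, coord_map=coord,
            )
        )
    return RegionAlignment(rows=out)


def naive_conserved_stop_frames(rows, anchor_col, c0, c1):
    """Independent oracle: per-row six-frame stop scan on gapless rows,
    intersected across rows; frames labelled relative to the anchor column."""
    per_row_stops = []
    for _, seq in rows:
        assert "-" not in seq
        stops = set()
        for frame in range(3):
            for i in range(frame, len(seq) - 2, 3):
                if seq[i : i + 3] in STOPS:
                    stops.add(i)
        per_row_stops.append(stops)
    conserved = set.intersection(*per_row_stops)
    counts = {"+1": 0, "+2": 0, "+3": 0}
    for col in sorted(conserved):
        if not (c0 <= col < c1 - 2):
            continue
        label = {0: "+1", 1: "+2", 2: "+3"}[(col - anchor_col) % 3]
        counts[label] += 1
    return counts


def build_frame_fixture():
    """Five identical rows: anchor ATG at column 3; 4 universal stops in the
    +2 frame, 2 in the +3 frame, none in +1 over the analysis window."""
    L = 120
    seq = ["C"] * L
    anchor = 3
    seq[anchor : anchor + 3] = "ATG"
    plus2_cols = [anchor + 3 * k + 1 for k in (4, 10, 16, 22)]
    plus3_cols = [anchor + 3 * k + 2 for k in (7, 13)]
    for c in plus2_cols:
        seq[c : c + 3] = "TAA"
    for c in plus3_cols:
        seq[c : c + 3] = "TGA"
    s = "".join(seq)
    rows = [(sp, s) for sp in ("sim", "sec", "mel", "yak", "ere")]
    return rows, anchor, (0, L)


class TestIntronMod3:
    def test_52_nt_intron_predates_orf(self):
        assert intron_mod3_test(52) == "predates_orf"

    def test_multiple_of_three_inconclusive(self):
        assert intron_mod3_test(51) == "inconclusive"

    def test_below_minimum_is_error(self):
        with pytest.raises(ValueError):
            intron_mod3_test(3)


class TestConservedStopFrames:
    def test_fixture_reproduces_0_4_2_pattern(self):
        rows, anchor, (c0, c1) = build_frame_fixture()
        aln = make_alignment(rows)
        conv = FrameConvention(anchor_species="sim", anchor_column=anchor)
        result = conserved_stop_frames(aln, conv, (c0, c1))
        assert result["counts"] == {"+1": 0, "+2": 4, "+3": 2}
        assert result["open_frames"] == {"+1"}
        assert result["ambiguous"] == []
        # independent naive six-frame scan agrees
        assert result["counts"] == naive_conserved_stop_frames(rows, anchor, c0, c1)

    def test_no_stops_leaves_all_frames_open(self):
        rows = [(sp, "C" * 60) for sp in ("a", "b", "c")]
        aln = make_alignment(rows)
        conv = FrameConvention(anchor_species="a", anchor_column=0)
        result = conserved_stop_frames(aln, conv, (0, 60))
        assert result["counts"] == {"+1": 0, "+2": 0, "+3": 0}
        assert result["open_frames"] == {"+1", "+2", "+3"}

    def test_one_divergent_row_breaks_conservation(self):
        rows, anchor, (c0, c1) = build_frame_fixture()
        # change one stop codon in one row to a sense codon
        sp, s = rows[2]
        col = s.index("TAA")
        rows[2] = (sp, s[:col] + "CAA" + s[col + 3 :])
        aln = make_alignment(rows)
        conv = FrameConvention(anchor_species="sim", anchor_column=anchor)
        result = conserved_stop_frames(aln, conv, (c0, c1))
        assert result["counts"] == {"+1": 0, "+2": 3, "+3": 2}

    def test_interior_indel_makes_frames_ambiguous(self):
        # a 1-nt gap in one row between anchor and a conserved stop shifts
        # that row's frame: the codon must be reported ambiguous, not counted
        base = "ATG" + "C" * 9 + "TAA" + "CCC"
        gapped_other = "ATG" + "C" * 8 + "-" + "TAA" + "CCC"
        aln = make_alignment([("a", base), ("b", gapped_other)])
        conv = FrameConvention(anchor_species="a", anchor_column=0)
        result = conserved_stop_frames(aln, conv, (0, len(base)))
        assert result["counts"] == {"+1": 0, "+2": 0, "+3": 0}
        assert result["ambiguous"] == [12]

    def test_invariant_to_row_order_and_gap_padding(self):
        rows, anchor, (c0, c1) = build_frame_fixture()
        aln1 = conserved_stop_frames(
            make_alignment(rows),
            FrameConvention("sim", anchor), (c0, c1),
        )
        aln2 = conserved_stop_frames(
            make_alignment(rows[::-1]),
            FrameConvention("sim", anchor), (c0, c1),
        )
        padded = [(sp, s + "----") for sp, s in rows]
        aln3 = conserved_stop_frames(
            make_alignment(padded),
            FrameConvention("sim", anchor), (c0, c1 + 4),
        )
        assert aln1["counts"] == aln2["counts"] == aln3["counts"]

    def test_no_conserved_stop_in_open_frames(self):
        rows, anchor, (c0, c1) = build_frame_fixture()
        result = conserved_stop_frames(
            make_alignment(rows), FrameConvention("sim", anchor), (c0, c1)
        )
        for frame in result["open_frames"]:
            assert result["stop_columns"][frame] == []


class TestDistantStartCheck:
    def test_absent_when_no_atg_near_start(self):
        cand = "CCC" + "ATG" + "C" * 60
        distant = "CCC" + "ATA" + "C" * 60
        aln = make_alignment([("cand", cand), ("far", distant)])
        out = distant_outgroup_start_check(aln, "cand", 3, ["far"])
        assert out == {"far": "absent"}

    def test_present_when_in_frame_atg_at_position(self):
        cand = "CCC" + "ATG" + "C" * 60
        aln = make_alignment([("cand", cand), ("far", cand)])
        out = distant_outgroup_start_check(aln, "cand", 3, ["far"])
        assert out == {"far": "present"}

    def test_out_of_frame_atg_not_counted(self):
        cand = "CCC" + "ATG" + "C" * 60
        # ATG one column off the candidate's frame
        distant = "CCCC" + "ATG" + "C" * 59
        aln = make_alignment([("cand", cand), ("far", distant)])
        out = distant_outgroup_start_check(aln, "cand", 3, ["far"])
        assert out == {"far": "absent"}

    def test_missing_row_unavailable(self):
        cand = "CCC" + "ATG" + "C" * 60
        aln = make_alignment([("cand", cand), ("other", cand)])
        out = distant_outgroup_start_check(aln, "cand", 3, ["far"])
        assert out == {"far": "unavailable"}


def _base_evidence(**kw):
    ev = OriginEvidence(family_id="f")
    ev.outgroup_orf_flag = False
    ev.alignment_continuous = {"yak": True, "ere": True}
    ev.outgroup_max_identity = 0.85
    ev.frame_analysis = {
        "counts": {"+1": 0, "+2": 0, "+3": 0},
        "open_frames": {"+1", "+2", "+3"},
        "ambiguous": [], "stop_columns": {"+1": [], "+2": [], "+3": []},
    }
    for k, v in kw.items():
        setattr(ev, k, v)
    return ev


class TestClassifyOrigin:
    def test_outgroup_orf_implies_earlier_origin(self):
        ev = _base_evidence(outgroup_orf_flag=True)
        assert classify_origin(ev).classification == "earlier_origin"

    def test_no_continuous_alignment_undetermined(self):
        ev = _base_evidence(alignment_continuous={"yak": False, "ere": False})
        assert classify_origin(ev).classification == "undetermined"

    def test_disrupted_outgroup_with_synteny_is_de_novo(self):
        ev = _base_evidence()
        assert classify_origin(ev).classification == "de_novo"

    def test_near_identical_outgroup_sharing_frame_is_diverged_ancestor(self):
        ev = _base_evidence(
            outgroup_max_identity=0.95,
            frame_analysis={
                "counts": {"+1": 0, "+2": 4, "+3": 2},
                "open_frames": {"+1"}, "ambiguous": [],
                "stop_columns": {"+1": [], "+2": [1, 2, 3, 4], "+3": [5, 6]},
            },
        )
        assert classify_origin(ev).classification == "diverged_ancestor"

    def test_same_frame_pattern_at_normal_divergence_stays_de_novo(self):
        # a genuinely de novo ORF also leaves conserved alternate-frame stops
        ev = _base_evidence(
            outgroup_max_identity=0.84,
            frame_analysis={
                "counts": {"+1": 0, "+2": 4, "+3": 2},
                "open_frames": {"+1"}, "ambiguous": [],
                "stop_columns": {"+1": [], "+2": [1, 2, 3, 4], "+3": [5, 6]},
            },
        )
        assert classify_origin(ev).classification == "de_novo"

    def test_distant_start_codon_blocks_de_novo(self):
        ev = _base_evidence(distant_outgroup_start_codons={"ana": "present"})
        out = classify_origin(ev)
        assert out.classification == "undetermined"

    def test_intragenomic_duplicates_block_de_novo(self):
        ev = _base_evidence(intragenomic_duplicate_flags={"yak": 2})
        assert classify_origin(ev).classification == "undetermined"


class TestSyntenyContext:
    def test_planted_locus_has_conserved_flanks(self, sim_clade):
        from trgscout.family_inference import (
            HomologyFamily, build_families, proteome_of,
        )

        genomes, truth = sim_clade
        proteomes = {sp: proteome_of(g) for sp, g in genomes.items()}
        families = build_families(proteomes)
        gene_to_family = {
            m: f.family_id for f in families for m in f.members
        }
        fam = next(
            f for f in families
            if ("sim", "dn1") in f.members
        )
        dn = truth[truth.locus_id == "dn1"].set_index("species")
        regions = {
            sp: ("chr1", Interval(int(dn.loc[sp].start), int(dn.loc[sp].end)))
            for sp in ("sim", "sec", "mel", "yak", "ere")
        }
        report = synteny_context(fam, regions, genomes, gene_to_family)
        assert report.synteny_ok
        assert report.shared_families
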