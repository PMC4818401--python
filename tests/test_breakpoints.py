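"""Junction interpretation: sizes, motifs, microhomology, mechanism."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarecnv.breakpoints import (
    JunctionReport,
    Mechanism,
    RepeatHomology,
    analyze_junction,
    classify_mechanism,
    event_size,
    find_flanking_repeat,
    junction_motif_scan,
    microhomology_length,
)
from rarecnv.simulate import generate_junction

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestEventSize:
    @pytest.mark.parametrize(
        "start,end,bp,kb",
        [
            (94_781_525, 94_797_285, 15_761, 15.8),
            (5_786_323, 5_905_210, 118_888, 119.0),
            (140_390_975, 140_524_875, 133_901, 134.0),
        ],
    )
    def test_reported_event_sizes(self, start, end, bp, kb):
        assert event_size(start, end) == (bp, kb)

    def test_invalid_interval_is_error(self):
        with pytest.raises(ValueError):
            event_size(100, 100)
        with pytest.raises(ValueError):
            event_size(100, 50)


class TestJunctionMotifScan:
    def test_planted_motif_reported_at_both_junctions(self):
        records, ann = generate_junction(
            deleted_len=2000, flank_len=200, planted_motif="GATCAC",
            repeat_homology_len=0, microhomology_len=0, seed=3,
        )
        ref = str(records[0].seq)
        s, e = ann["del_start"], ann["del_end"]
        left_win = ref[s - 1 - 50 : s - 1]
        right_win = ref[e - 50 : e]
        hits = junction_motif_scan(left_win, right_win)
        gat = [m for m in hits if m.kmer == "GATCAC"]
        assert gat and gat[0].left_offset == 0 and gat[0].right_offset == 0

    def test_identical_flanks_give_single_maximal_window(self):
        seq = "ACGTACGTACGTACGTACGT"
        hits = junction_motif_scan(seq, seq, k_min=4, k_max=30, window=len(seq))
        assert hits[0].kmer == seq
        # every other hit is an off-diagonal repeat of the periodic sequence,
        # never a same-offset substring of the full match
        assert all(h.left_offset != h.right_offset for h in hits[1:])

    def test_disjoint_alphabets_share_nothing(self):
        assert junction_motif_scan("A" * 30, "C" * 30) == []

    def test_n_never_matches(self):
        assert junction_motif_scan("ANNNA" * 5, "ANNNA" * 5, k_min=4) == []

    def test_rejects_non_nucleotide_characters(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            junction_motif_scan("ACGTX", "ACGT")

    @given(dna, dna)
    def test_matches_brute_force_shared_kmer_sets(self, left, right):
        k_min, k_max, window = 4, 12, 40
        hits = junction_motif_scan(left, right, k_min, k_max, window)
        lwin, rwin = left[-window:], right[-window:]
        brute = set()
        for k in range(k_min, k_max + 1):
            lset = {lwin[i : i + k] for i in range(max(0, len(lwin) - k + 1))}
            rset = {rwin[i : i + k] for i in range(max(0, len(rwin) - k + 1))}
            brute |= {km for km in lset & rset if len(km) == k}
        reported = {m.kmer for m in hits}
        # every reported k-mer is genuinely shared
        assert reported <= brute
        # every shared k-mer is either reported or inside a reported one
        for km in brute:
            assert any(km in rep for rep in reported)


class TestMicrohomology:
    def test_planted_six_base_microhomology(self):
        records, ann = generate_junction(
            deleted_len=500, flank_len=100, planted_motif="",
            microhomology_len=6, seed=5,
        )
        ref = str(records[0].seq)
        assert microhomology_length(ref, ann["del_start"], ann["del_end"]) == 6

    def test_differing_first_bases_give_zero(self):
        #           1234567890
        ref = "AAAACTTTTTGGGG"
        # deletion of [5..10]: junction prefixes are "CTTTT..." vs "GGGG"
        assert microhomology_length(ref, 5, 10) == 0

    def test_deleting_one_copy_of_tandem_repeat_gives_unit_length(self):
        unit = "GATTACA"
        ref = "CCCC" + unit + unit + "TTTT"
        # delete exactly the first copy: positions 5..11
        assert microhomology_length(ref, 5, 11) == len(unit)

    def test_invariant_under_appending_unrelated_sequence(self):
        ref = "ACGT" + "GATCAC" + "TTTTCCCC" + "GATCACGGA"
        base = microhomology_length(ref, 5, 18)
        assert microhomology_length(ref + "ACGTACGT", 5, 18) == base

    def test_out_of_bounds_is_error(self):
        with pytest.raises(ValueError):
            microhomology_length("ACGTACGT", 5, 20)


class TestFlankingRepeat:
    def test_planted_repeat_recovered_near_requested_identity(self):
        records, ann = generate_junction(
            deleted_len=2000, flank_len=610, planted_motif="",
            repeat_homology_len=300, repeat_identity=0.9, microhomology_len=0, seed=9,
        )
        ref = str(records[0].seq)
        s, e = ann["del_start"], ann["del_end"]
        left = ref[s - 1 - 610 : s - 1]
        right = ref[e : e + 610]
        hit = find_flanking_repeat(left, right)
        assert hit.length >= 200
        assert hit.identity >= 0.85

    def test_unrelated_flanks_have_no_long_homology(self):
        import numpy as np

        rng = np.random.default_rng(4)
        left = "".join(rng.choice(list("ACGT"), 600))
        right = "".join(rng.choice(list("ACGT"), 600))
        hit = find_flanking_repeat(left, right)
        assert hit.length < 100


class TestClassifyMechanism:
    def test_nahr_when_repeats_qualify(self):
        report = JunctionReport(
            microhomology=0,
            repeat_homology=RepeatHomology(length=300, identity=0.9, left_offset=0, right_offset=0),
        )
        assert classify_mechanism(report).mechanism is Mechanism.NAHR

    @pytest.mark.parametrize(
        "mh,expected",
        [(0, Mechanism.NHEJ), (1, Mechanism.NHEJ), (2, Mechanism.MMEJ),
         (5, Mechanism.MMEJ), (10, Mechanism.MMEJ), (11, Mechanism.UNCLASSIFIED)],
    )
    def test_microhomology_bands_without_repeats(self, mh, expected):
        report = JunctionReport(microhomology=mh)
        assert classify_mechanism(report).mechanism is expected

    def test_classification_is_total_and_echoes_thresholds(self):
        for mh in range(0, 15):
            for length, ident in [(0, 0.0), (150, 0.8), (150, 0.95), (50, 0.99)]:
                report = JunctionReport(
                    microhomology=mh,
                    repeat_homology=RepeatHomology(length=length, identity=ident),
                )
                out = classify_mechanism(report)
                assert out.mechanism in Mechanism
                assert out.thresholds["min_repeat_len"] == 100


class TestAnalyzeJunction:
    def test_full_workup_of_nahr_like_fixture(self):
        records, ann = generate_junction(
            deleted_len=2000, flank_len=610, planted_motif="GATCAC",
            repeat_homology_len=300, repeat_identity=0.9, microhomology_len=0, seed=1,
        )
        report = analyze_junction(
            str(records[0].seq), ann["del_start"], ann["del_end"], flank_len=610
        )
        assert report.event_bp == 2000
        assert report.mechanism is Mechanism.NAHR
        assert any(m.kmer == "GATCAC" for m in report.shared_motifs)

    def test_mmej_like_fixture(self):
        records, ann = generate_junction(
            deleted_len=2000, flank_len=610, planted_motif="",
            repeat_homology_len=0, microhomology_len=5, seed=2,
        )
        report = analyze_junction(
            str(records[0].seq), ann["del_start"], ann["del_end"], flank_len=610
        )
        assert report.microhomology == 5
        assert report.mechanism is Mechanism.MMEJ
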