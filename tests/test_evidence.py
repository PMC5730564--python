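"""SL/poly(A) read tagging, pileup, peak calling and RPKM."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbone.errors import ParameterError, ValidationError
from tbone.evidence import (
    call_peaks,
    compute_rpkm,
    detect_and_trim_sl,
    detect_polya_tail,
    pileup_end_positions,
)


def _tag_one_sl(seq, leader, **kw):
    (read,) = list(detect_and_trim_sl([("r", seq)], leader, **kw))
    return read


class TestSlDetection:
    @pytest.mark.parametrize(
        "read,min_match,max_mismatch,kind,trimmed",
        [
            ("TTTAA" + "ACGTACGTACGTACGTACGT", 5, 0, "SL", 5),  # exact suffix match
            ("CCCCC" + "ACGTACGTACGTACGTACGT", 5, 0, "NONE", 0),  # no leader prefix
            ("TTAAG" + "ACGTACGTACGTACGTACGT", 5, 0, "NONE", 0),  # only 4-nt suffix
        ],
    )
    def test_suffix_prefix_rule(self, read, min_match, max_mismatch, kind, trimmed):
        tagged = _tag_one_sl(
            read, "GGTTTAA", min_match=min_match, max_mismatch=max_mismatch
        )
        assert tagged.evidence_kind == kind
        assert tagged.trimmed_prefix_len == trimmed

    def test_longest_suffix_wins(self):
        leader = "GGTTTAA"
        read = leader + "A" * 25
        tagged = _tag_one_sl(read, leader, min_match=5, max_mismatch=0)
        assert tagged.trimmed_prefix_len == len(leader)

    def test_mismatch_tolerance(self):
        leader = "GGTTTAACTACGGGAGTTTG"
        read = "GAGTTTC" + "C" * 30  # 7-nt suffix with one mismatch at the end
        tagged = _tag_one_sl(read, leader, min_match=7, max_mismatch=1)
        assert tagged.evidence_kind == "SL"

    def test_short_remainder_not_usable(self):
        leader = "GGTTTAA"
        tagged = _tag_one_sl(leader + "ACGT", leader, min_match=5, max_mismatch=0)
        assert tagged.evidence_kind == "NONE"

    def test_empty_leader_rejected(self):
        with pytest.raises(ParameterError):
            list(detect_and_trim_sl([("r", "ACGT")], ""))


class TestPolyaDetection:
    def test_tail_trimmed(self):
        (read,) = list(detect_polya_tail([("r", "CCGTCCGT" + "A" * 7)], min_a_run=5))
        assert read.evidence_kind == "POLYA"
        assert read.trimmed_prefix_len == 7
        assert read.sequence == "CCGTCCGT"

    def test_below_run_length(self):
        (read,) = list(detect_polya_tail([("r", "CCGTCCGTAAAA")], min_a_run=5))
        assert read.evidence_kind == "NONE"
        assert read.sequence == "CCGTCCGTAAAA"

    def test_pretagged_tfill_without_tail(self):
        (read,) = list(
            detect_polya_tail([("r", "CCGTCCGT")], min_a_run=5, assume_tfill=True)
        )
        assert read.evidence_kind == "POLYA"

    def test_interrupted_tail(self):
        (read,) = list(
            detect_polya_tail([("r", "CCGT" + "AAAGAAAA")], min_a_run=5, max_non_a=1)
        )
        assert read.evidence_kind == "POLYA"
        assert read.sequence == "CCGT"


class TestPileup:
    def test_accumulation(self):
        track = pileup_end_positions([("s1", "+", 100)] * 3, "SL")
        assert track.counts[("s1", "+")] == {100: 3}
        assert track.total() == 3

    def test_strands_kept_separate(self):
        track = pileup_end_positions([("s1", "+", 7), ("s1", "-", 7)], "POLYA")
        assert track.counts[("s1", "+")] == {7: 1}
        assert track.counts[("s1", "-")] == {7: 1}

    def test_empty_stream(self):
        assert pileup_end_positions([], "SL").total() == 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            pileup_end_positions([("s1", "+", 10)], "SL", genome={"s1": "ACGT"})


def _brute_force_groups(positions, merge_distance):
    """Independent oracle: the unique partition of sorted positions into
    contiguous groups such that within-group gaps are <= merge_distance and
    cross-boundary gaps are > merge_distance, found by checking every
    possible set of cut points."""
    import itertools

    positions = sorted(positions)
    n = len(positions)
    for cuts in itertools.product([False, True], repeat=max(0, n - 1)):
        groups, current = [], [positions[0]]
        ok = True
        for i, cut in enumerate(cuts):
            gap = positions[i + 1] - positions[i]
            if cut:
                if gap <= merge_distance:
                    ok = False
                    break
                groups.append(current)
                current = [positions[i + 1]]
            else:
                if gap > merge_distance:
                    ok = False
                    break
                current.append(positions[i + 1])
        if ok:
            groups.append(current)
            return groups
    raise AssertionError("no valid partition found")


class TestPeakCalling:
    def test_adjacent_positions_merge(self):
        track = pileup_end_positions(
            [("s1", "+", 100)] * 7 + [("s1", "+", 101)] * 2, "SL"
        )
        (peak,) = call_peaks(track, min_site_count=5, merge_distance=10)
        assert (peak.summit, peak.total_count) == (100, 9)

    def test_weak_isolated_groups_dropped(self):
        track = pileup_end_positions(
            [("s1", "+", 100)] * 2 + [("s1", "+", 200)] * 2, "SL"
        )
        assert call_peaks(track, min_site_count=5, merge_distance=10) == []

    def test_grouping_matches_brute_force_oracle(self):
        placements = (
            [("s1", "+", 100)] * 4 + [("s1", "+", 104)] * 4 + [("s1", "+", 130)] * 6
        )
        track = pileup_end_positions(placements, "SL")
        peaks = call_peaks(track, min_site_count=5, merge_distance=10)
        oracle = _brute_force_groups([p for _, _, p in placements], 10)
        counts = {100: 4, 104: 4, 130: 6}
        expected_totals = sorted(
            sum(counts[p] for p in set(g))
            for g in oracle
            if sum(counts[p] for p in set(g)) >= 5
        )
        assert sorted(p.total_count for p in peaks) == expected_totals == [6, 8]

    def test_summit_tie_breaks_5prime(self):
        plus = pileup_end_positions([("s1", "+", 10)] * 3 + [("s1", "+", 12)] * 3, "SL")
        minus = pileup_end_positions([("s1", "-", 10)] * 3 + [("s1", "-", 12)] * 3, "SL")
        assert call_peaks(plus, 5, 10)[0].summit == 10
        assert call_peaks(minus, 5, 10)[0].summit == 12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        positions=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 8)), min_size=1, max_size=30
        ),
        min_count=st.integers(1, 12),
        merge=st.integers(0, 20),
    )
    def test_conservation_and_monotonicity(self, positions, min_count, merge):
        track = pileup_end_positions(
            [("s1", "+", p) for p, c in positions for _ in range(c)], "SL"
        )
        peaks = call_peaks(track, min_count, merge)
        # conservation: peak totals + discarded-group totals == track total
        all_groups = call_peaks(track, 1, merge)
        assert sum(p.total_count for p in all_groups) == track.total()
        assert sum(p.total_count for p in peaks) <= track.total()
        # monotonicity: raising min_site_count never adds peaks
        assert len(call_peaks(track, min_count + 3, merge)) <= len(peaks)

    def test_exact_recovery_on_clean_fixture(self, clean_sim):
        track = pileup_end_positions(clean_sim.sl_placements, "SL")
        peaks = call_peaks(track, min_site_count=5, merge_distance=10)
        summits = {(p.interval.scaffold_id, p.interval.strand, p.summit) for p in peaks}
        for g in clean_sim.truth.genes:
            if g.has_evidence and g.sl_reads >= 5:
                assert (g.scaffold, g.strand, g.sl_pos) in summits


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [(10, 1000, 10**6, 10.0), (0, 1000, 10**6, 0.0), (5, 2000, 10**7, 0.25)],
    )
    def test_formula(self, reads, length, total, expected):
        assert compute_rpkm(reads, length, total) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ParameterError):
            compute_rpkm(1, 0, 100)
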