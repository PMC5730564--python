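"""Longest-ORF calling and ORF/poly(A)-aware merging."""

import itertools

import numpy as np
import pytest

from tbone.errors import ValidationError
from tbone.models import GenomicInterval, OrfRecord, RepeatMask
from tbone.orfs import (
    STOP_CODONS,
    find_longest_orf,
    merge_split_transcripts,
    transcript_sequence,
    translate_cds,
)

from conftest import make_gene


def brute_force_longest_orf(seq, min_aa):
    """Independent oracle: enumerate every ATG..stop span in the 3 forward
    frames and pick the longest qualifying one (ties 5'-most)."""
    seq = seq.upper()
    candidates = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for end in range(start + 3, len(seq) - 2, 3):
            if seq[end : end + 3] in STOP_CODONS:
                n_aa = (end - start) // 3
                if n_aa >= min_aa:
                    candidates.append((n_aa, -start, start, end + 3))
                break
    if not candidates:
        return None
    _, _, start, end = max(candidates)
    return (start, end)


class TestFindLongestOrf:
    def test_simple_complete_orf(self):
        orf = find_longest_orf("ATGAAATAA", min_aa=2)
        assert orf == OrfRecord(0, 9, 0, "MK", True)

    def test_below_min_aa_returns_nothing(self):
        assert find_longest_orf("CCCATGTAA", min_aa=2) is None

    def test_orf_without_stop_not_called(self):
        assert find_longest_orf("ATG" + "AAA" * 10, min_aa=2) is None

    def test_frame_offsets(self):
        orf = find_longest_orf("CCATGAAAAAATAG", min_aa=2)
        assert orf.frame == 2
        assert orf.protein == "MKK"

    def test_tie_breaks_five_prime(self):
        seq = "ATGAAATAA" + "C" + "ATGAAATAA"
        orf = find_longest_orf(seq, min_aa=2)
        assert orf.start == 0

    def test_too_short_sequence(self):
        assert find_longest_orf("AT", min_aa=1) is None

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, size=500)])
            got = find_longest_orf(seq, min_aa=10)
            expected = brute_force_longest_orf(seq, min_aa=10)
            if expected is None:
                assert got is None
            else:
                assert (got.start, got.end) == expected
                assert translate_cds(seq[got.start : got.end]) == got.protein


def split_pair(orf_a, polya_a, orf_b, polya_b, gap=2000, strand="+"):
    """Two adjacent gene models on one strand with configurable evidence."""
    fake_orf = OrfRecord(0, 9, 0, "MK", True)
    if strand == "+":
        a = make_gene("A", "s1", "+", [(1000, 2000)], has_polya=polya_a)
        b = make_gene("B", "s1", "+", [(2000 + gap, 3000 + gap)], has_polya=polya_b)
    else:
        # transcript orientation right-to-left: upstream A is genomic-right
        b = make_gene("B", "s1", "-", [(1000, 2000)], has_polya=polya_b)
        a = make_gene("A", "s1", "-", [(2000 + gap, 3000 + gap)], has_polya=polya_a)
    a.orf = fake_orf if orf_a else None
    b.orf = fake_orf if orf_b else None
    return [a, b]


def full_repeat_mask():
    return RepeatMask([GenomicInterval("s1", 0, 100_000, ".")])


class TestMergeSplitTranscripts:
    def test_stated_combination_merges(self):
        genes = split_pair(True, False, False, True, gap=2000)
        merged, events = merge_split_transcripts(genes, full_repeat_mask())
        assert len(merged) == 1
        assert len(events) == 1
        assert merged[0].has_polya_3p
        assert merged[0].interval.start == 1000 and merged[0].interval.end == 5000
        assert len(merged[0].exons) == 2  # gap recorded as intron

    def test_gap_above_10kb_blocks_merge(self):
        genes = split_pair(True, False, False, True, gap=12_000)
        merged, events = merge_split_transcripts(genes, full_repeat_mask())
        assert len(merged) == 2 and not events

    def test_nonrepetitive_gap_blocks_merge(self):
        genes = split_pair(True, False, False, True, gap=2000)
        merged, events = merge_split_transcripts(genes, RepeatMask([]))
        assert len(merged) == 2 and not events

    @pytest.mark.parametrize(
        "combo", list(itertools.product([False, True], repeat=4))
    )
    def test_condition_truth_table(self, combo):
        """Of all 16 evidence combinations only (ORF_A, no polyA_A, no ORF_B,
        polyA_B) merges."""
        genes = split_pair(*combo, gap=2000)
        merged, events = merge_split_transcripts(genes, full_repeat_mask())
        should_merge = combo == (True, False, False, True)
        assert (len(merged) == 1) is should_merge
        assert bool(events) is should_merge

    def test_minus_strand_orientation(self):
        genes = split_pair(True, False, False, True, gap=2000, strand="-")
        merged, events = merge_split_transcripts(genes, full_repeat_mask())
        assert len(merged) == 1
        assert merged[0].gene_id == "A"

    def test_merge_preserves_exonic_length_and_counts(self):
        genes = split_pair(True, False, False, True, gap=2000)
        before = sum(g.exonic_length for g in genes)
        merged, events = merge_split_transcripts(genes, full_repeat_mask())
        assert sum(g.exonic_length for g in merged) >= before
        assert len(merged) == len(genes) - len(events)

    def test_overlapping_inputs_rejected(self):
        a = make_gene("A", "s1", "+", [(1000, 2500)])
        b = make_gene("B", "s1", "+", [(2000, 3000)])
        with pytest.raises(ValidationError, match="overlapping"):
            merge_split_transcripts([a, b], RepeatMask([]))

    def test_orf_recalled_on_merged_sequence(self):
        genes = split_pair(True, False, False, True, gap=2000)
        genome = {"s1": "T" * 100_000}
        chars = list(genome["s1"])
        cds = "ATG" + "GAA" * 40 + "TAA"  # spans the junction after splicing
        chars[1900 : 1900 + 100] = cds[:100]
        chars[4000 : 4000 + len(cds) - 100] = cds[100:]
        genome = {"s1": "".join(chars)}
        merged, events = merge_split_transcripts(
            genes, full_repeat_mask(), genome=genome, min_aa=40
        )
        assert len(merged) == 1
        assert merged[0].orf is not None
        assert merged[0].orf.protein == "M" + "E" * 40


def test_transcript_sequence_is_spliced_and_stranded():
    genome = {"s1": "AAACCCGGGTTT"}
    plus = make_gene("p", "s1", "+", [(0, 3), (6, 9)])
    minus = make_gene("m", "s1", "-", [(0, 3), (6, 9)])
    assert transcript_sequence(plus, genome) == "AAAGGG"
    assert transcript_sequence(minus, genome) == "CCCTTT"
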