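"""Duplicated-block detection on masked genomes."""

import numpy as np
import pytest

from tbone.dup import duplicated_fraction, find_dup_blocks, mask_genome
from tbone.models import DupBlock, GenomicInterval, RepeatMask, revcomp

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def nw_identity_oracle(a, b):
    """Brute-force global alignment identity (matches / columns) by
    Needleman-Wunsch dynamic programming, independent of the implementation's
    alignment library."""
    n, m = len(a), len(b)
    dist = np.zeros((n + 1, m + 1), dtype=int)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1, j - 1] + (a[i - 1] != b[j - 1])
            dist[i, j] = min(sub, dist[i - 1, j] + 1, dist[i, j - 1] + 1)
    # traceback counting matches and columns
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


class TestMaskGenome:
    def test_prefix_mask(self):
        mask = RepeatMask([GenomicInterval("s1", 0, 5, ".")])
        assert mask_genome({"s1": "ACGTACGTAC"}, mask)["s1"] == "NNNNNCGTAC"

    def test_empty_mask_is_identity(self):
        assert mask_genome({"s1": "ACGT"}, RepeatMask([]))["s1"] == "ACGT"

    def test_full_mask(self):
        mask = RepeatMask([GenomicInterval("s1", 0, 4, ".")])
        assert mask_genome({"s1": "ACGT"}, mask)["s1"] == "NNNN"


def plant(rng, length, identity, orientation, scaffold_len=20_000):
    """Two scaffolds with one planted duplication; returns (genome, truth)."""
    g1 = list(random_seq(rng, scaffold_len))
    g2 = list(random_seq(rng, scaffold_len))
    a0, b0 = 5000, 8000
    src = "".join(g1[a0 : a0 + length])
    copy = list(src if orientation == "same" else revcomp(src))
    n_sub = int(round(length * (1 - identity)))
    if n_sub:
        for p in rng.choice(length, size=n_sub, replace=False):
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
    g2[b0 : b0 + length] = copy
    # sharp boundaries: flanks of the copy must not extend the block
    if orientation == "same":
        g2[b0 - 1] = "A" if g1[a0 - 1] != "A" else "C"
        g2[b0 + length] = "A" if g1[a0 + length] != "A" else "C"
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        g2[b0 - 1] = "A" if comp[g1[a0 + length]] != "A" else "C"
        g2[b0 + length] = "A" if comp[g1[a0 - 1]] != "A" else "C"
    genome = {"s1": "".join(g1), "s2": "".join(g2)}
    return genome, (a0, b0, length, 1 - (n_sub / length))


class TestFindDupBlocks:
    def test_exact_600nt_duplication_found(self):
        rng = np.random.default_rng(20)
        genome, (a0, b0, length, _) = plant(rng, 600, 1.0, "same")
        (blk,) = find_dup_blocks(genome)
        assert blk.identity == pytest.approx(1.0)
        assert blk.aligned_length == 600
        assert (blk.interval_a.start, blk.interval_b.start) == (a0, b0)

    def test_400nt_copy_rejected_by_length(self):
        rng = np.random.default_rng(21)
        genome, _ = plant(rng, 400, 1.0, "same")
        assert find_dup_blocks(genome) == []

    def test_93_percent_block_rejected_by_identity(self):
        rng = np.random.default_rng(22)
        genome, (a0, b0, length, realized) = plant(rng, 600, 1 - 40 / 600, "same")
        assert realized == pytest.approx(0.9333, abs=1e-3)
        assert find_dup_blocks(genome) == []
        # confirm with the brute-force alignment oracle over the planted loci
        oracle = nw_identity_oracle(
            genome["s1"][a0 : a0 + length], genome["s2"][b0 : b0 + length]
        )
        assert oracle < 0.95

    def test_inverted_duplication_found(self):
        rng = np.random.default_rng(23)
        genome, (a0, b0, length, _) = plant(rng, 700, 0.98, "inverted")
        (blk,) = find_dup_blocks(genome)
        assert blk.orientation == "inverted"
        assert blk.aligned_length > 500
        assert blk.identity >= 0.95

    def test_reported_identity_close_to_alignment_oracle(self):
        rng = np.random.default_rng(24)
        genome, _ = plant(rng, 650, 0.97, "same")
        (blk,) = find_dup_blocks(genome)
        a = genome[blk.interval_a.scaffold_id][blk.interval_a.start : blk.interval_a.end]
        b = genome[blk.interval_b.scaffold_id][blk.interval_b.start : blk.interval_b.end]
        assert blk.identity == pytest.approx(nw_identity_oracle(a, b), abs=0.005)

    def test_masked_duplication_invisible(self):
        rng = np.random.default_rng(25)
        genome, (a0, b0, length, _) = plant(rng, 600, 1.0, "same")
        masked = mask_genome(genome, RepeatMask([GenomicInterval("s1", a0, a0 + length, ".")]))
        assert find_dup_blocks(masked) == []

    def test_scaffold_reordering_invariance(self):
        rng = np.random.default_rng(26)
        genome, _ = plant(rng, 600, 0.98, "same")
        forward = find_dup_blocks(dict(sorted(genome.items())))
        reversed_order = find_dup_blocks(dict(sorted(genome.items(), reverse=True)))
        assert forward == reversed_order

    def test_tandem_self_overlap_discarded(self):
        rng = np.random.default_rng(27)
        seq = random_seq(rng, 3000)
        # an overlapping "copy": the same locus shifted by 100 nt
        genome = {"s1": seq[:2000] + seq[1000:1900] + seq[2000:]}
        blocks = find_dup_blocks(genome)
        for blk in blocks:
            assert not blk.interval_a.overlaps(blk.interval_b)


class TestDuplicatedFraction:
    def test_union_arithmetic(self):
        blk = DupBlock(
            GenomicInterval("s1", 0, 600, "."),
            GenomicInterval("s1", 5000, 5600, "."),
            "same",
            1.0,
            600,
        )
        nt, frac = duplicated_fraction([blk], {"s1": "A" * 10_000})
        assert (nt, frac) == (1200, 0.12)

    def test_overlapping_blocks_counted_once(self):
        blocks = [
            DupBlock(
                GenomicInterval("s1", 0, 600, "."),
                GenomicInterval("s1", 5000, 5600, "."),
                "same",
                1.0,
                600,
            ),
            DupBlock(
                GenomicInterval("s1", 0, 600, "."),
                GenomicInterval("s1", 7000, 7600, "."),
                "same",
                1.0,
                600,
            ),
        ]
        nt, _ = duplicated_fraction(blocks, {"s1": "A" * 10_000})
        assert nt == 1800

    def test_no_blocks(self):
        assert duplicated_fraction([], {"s1": "ACGT"}) == (0, 0.0)

    def test_exclude_repeat_positions(self):
        blk = DupBlock(
            GenomicInterval("s1", 0, 600, "."),
            GenomicInterval("s1", 5000, 5600, "."),
            "same",
            1.0,
            600,
        )
        mask = RepeatMask([GenomicInterval("s1", 0, 100, ".")])
        nt, _ = duplicated_fraction([blk], {"s1": "A" * 10_000}, mask, include_repeats=False)
        assert nt == 1100
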