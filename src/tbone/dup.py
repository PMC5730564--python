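"""Detection of duplicated non-repetitive genomic blocks.

The repeat-masked assembly is compared against itself: exact k-mer anchors
between distinct loci are chained collinearly (both orientations), chains are
extended ungapped with an X-drop rule, and candidate locus pairs are globally
aligned to measure identity.  Blocks longer than 500 nt and at least 95%
identical are reported (non-self: a block whose two intervals overlap is a
tandem self-hit and is discarded).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .alignment import identity_over_columns
from .errors import ParameterError
from .models import DupBlock, GenomeSequence, GenomicInterval, RepeatMask, revcomp

DEFAULT_K = 16
DEFAULT_MIN_LEN = 500
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_CHAIN_GAP = 100
DEFAULT_MAX_KMER_OCC = 50

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _as_dict(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return {g.scaffold_id: g.sequence for g in genome}


def mask_genome(
    genome: dict[str, str] | Sequence[GenomeSequence], repeat_mask: RepeatMask
) -> dict[str, str]:
    """Replace repeat-masked positions with N; length preserved."""
    genome = _as_dict(genome)
    out = {}
    for scaf, seq in genome.items():
        chars = None
        for iv in repeat_mask.intervals:
            if iv.scaffold_id != scaf:
                continue
            if chars is None:
                chars = list(seq)
            for i in range(iv.start, min(iv.end, len(seq))):
                chars[i] = "N"
        out[scaf] = "".join(chars) if chars is not None else seq
    return out


def _kmer_index(genome: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for scaf in sorted(genome):
        seq = genome[scaf]
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            index.setdefault(km, []).append((scaf, i))
    return index


def _extend_same(
    sa: str, sb: str, a0: int, a1: int, b0: int, b1: int
) -> tuple[int, int, int, int]:
    """Exact-match extension of a same-orientation anchor span.

    The collinear anchor chain already covers a block's interior (interior
    mismatches sit between anchors), so extension only needs to recover the
    terminal exact-match runs; stopping at the first mismatch keeps block
    boundaries deterministic.
    """
    off = 0
    while (
        a1 + off < len(sa)
        and b1 + off < len(sb)
        and sa[a1 + off] == sb[b1 + off]
        and sa[a1 + off] != "N"
    ):
        off += 1
    a1 += off
    b1 += off
    off = 0
    while (
        a0 - off - 1 >= 0
        and b0 - off - 1 >= 0
        and sa[a0 - off - 1] == sb[b0 - off - 1]
        and sa[a0 - off - 1] != "N"
    ):
        off += 1
    return a0 - off, a1, b0 - off, b1


def _extend_inverted(
    sa: str, sb: str, a0: int, a1: int, b0: int, b1: int
) -> tuple[int, int, int, int]:
    """Exact-match extension when locus B is the reverse complement of A:
    extending A rightward extends B leftward, and vice versa."""
    off = 0
    while (
        a1 + off < len(sa)
        and b0 - off - 1 >= 0
        and sa[a1 + off] == _COMP[sb[b0 - off - 1]]
        and sa[a1 + off] != "N"
    ):
        off += 1
    a1 += off
    b0 -= off
    off = 0
    while (
        a0 - off - 1 >= 0
        and b1 + off < len(sb)
        and sa[a0 - off - 1] == _COMP[sb[b1 + off]]
        and sa[a0 - off - 1] != "N"
    ):
        off += 1
    return a0 - off, a1, b0, b1 + off


def find_dup_blocks(
    genome: dict[str, str] | Sequence[GenomeSequence],
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    chain_gap: int = DEFAULT_CHAIN_GAP,
    max_kmer_occ: int = DEFAULT_MAX_KMER_OCC,
) -> list[DupBlock]:
    """Self-comparison of a (masked) genome for duplicated blocks.

    k-mers occurring more than ``max_kmer_occ`` times are skipped as
    unmasked high-copy sequence.  Results are invariant under scaffold
    reordering of the input (all iteration is over sorted scaffold ids).
    """
    if k < 12:
        raise ParameterError(f"anchor k must be >= 12; got {k}")
    if min_len <= k:
        raise ParameterError("min_len must exceed k")
    genome = _as_dict(genome)
    index = _kmer_index(genome, k)

    # anchors grouped by (scafA, scafB, orientation, diagonal)
    groups: dict[tuple, set[tuple[int, int]]] = {}

    def add_anchor(a: tuple[str, int], b: tuple[str, int], orient: str) -> None:
        if a == b:
            return
        if a > b:
            a, b = b, a
        (sa, pa), (sb, pb) = a, b
        diag = pb - pa if orient == "same" else pb + pa
        groups.setdefault((sa, sb, orient, diag), set()).add((pa, pb))

    for km in sorted(index):
        occ = index[km]
        if len(occ) > max_kmer_occ:
            continue
        for i in range(len(occ)):
            for j in range(i + 1, len(occ)):
                add_anchor(occ[i], occ[j], "same")
        rkm = revcomp(km)
        if rkm in index and km <= rkm:
            rocc = index[rkm]
            if len(rocc) > max_kmer_occ:
                continue
            for a in occ:
                for b in rocc:
                    add_anchor(a, b, "inverted")

    candidates: list[tuple[str, int, int, str, int, int, str]] = []
    for (sa, sb, orient, _diag), anchors in sorted(groups.items()):
        ordered = sorted(anchors)
        chain: list[tuple[int, int]] = []
        chains: list[list[tuple[int, int]]] = []
        for pa, pb in ordered:
            if chain and pa - chain[-1][0] > chain_gap + k:
                chains.append(chain)
                chain = []
            chain.append((pa, pb))
        if chain:
            chains.append(chain)
        for ch in chains:
            a0 = ch[0][0]
            a1 = ch[-1][0] + k
            bs = [pb for _, pb in ch]
            b0, b1 = min(bs), max(bs) + k
            seq_a, seq_b = genome[sa], genome[sb]
            if orient == "same":
                a0, a1, b0, b1 = _extend_same(seq_a, seq_b, a0, a1, b0, b1)
            else:
                a0, a1, b0, b1 = _extend_inverted(seq_a, seq_b, a0, a1, b0, b1)
            candidates.append((sa, a0, a1, sb, b0, b1, orient))

    blocks: list[DupBlock] = []

    def redundant(cand: DupBlock) -> bool:
        for kept in blocks:
            if kept.orientation != cand.orientation:
                continue
            ov_a = kept.interval_a.overlap_nt(cand.interval_a)
            ov_b = kept.interval_b.overlap_nt(cand.interval_b)
            if (
                ov_a >= 0.5 * cand.interval_a.length
                and ov_b >= 0.5 * cand.interval_b.length
            ):
                return True
        return False

    scored = []
    for sa, a0, a1, sb, b0, b1, orient in candidates:
        iv_a = GenomicInterval(sa, a0, a1, ".")
        iv_b = GenomicInterval(sb, b0, b1, ".")
        if iv_a.overlaps(iv_b):
            continue  # tandem self-hit
        if iv_a.sort_key() > iv_b.sort_key():
            iv_a, iv_b = iv_b, iv_a
        if min(iv_a.length, iv_b.length) <= min_len // 2:
            continue  # too short to ever qualify; skip the alignment
        seq_a = genome[sa][iv_a.start : iv_a.end]
        seq_b = genome[iv_b.scaffold_id][iv_b.start : iv_b.end]
        if orient == "inverted":
            seq_b = revcomp(seq_b)
        identity, columns = identity_over_columns(seq_a, seq_b)
        if columns > min_len and identity >= min_identity:
            scored.append(
                DupBlock(
                    interval_a=iv_a,
                    interval_b=iv_b,
                    orientation=orient,
                    identity=identity,
                    aligned_length=columns,
                )
            )
    for cand in sorted(
        scored, key=lambda blk: (-blk.aligned_length, blk.interval_a.sort_key())
    ):
        if not redundant(cand):
            blocks.append(cand)
    blocks.sort(key=lambda blk: (blk.interval_a.sort_key(), blk.interval_b.sort_key()))
    return blocks


def duplicated_fraction(
    blocks: Iterable[DupBlock],
    genome: dict[str, str] | Sequence[GenomeSequence],
    repeat_mask: Optional[RepeatMask] = None,
    include_repeats: bool = True,
) -> tuple[int, float]:
    """Genomic positions covered by at least one block side (union), and the
    fraction of the genome they represent.

    With ``include_repeats=False`` masked positions are excluded from the
    count even when a block covers them.
    """
    genome = _as_dict(genome)
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        for iv in (blk.interval_a, blk.interval_b):
            per_scaffold.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
    total = 0
    for scaf, ivs in per_scaffold.items():
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            span = e - s
            if not include_repeats and repeat_mask is not None:
                span -= repeat_mask.coverage_nt(scaf, s, e)
            total += span
    genome_len = sum(len(seq) for seq in genome.values())
    return total, (total / genome_len if genome_len else 0.0)
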