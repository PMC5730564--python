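"""Expression-based transcript filters.

Two filters are applied to assembled transcriptional units:

* antisense filtering — where transcripts on opposite strands share genomic
  coordinates, the lower-expressing strand is discarded when the read-count
  difference is at least fivefold (spurious antisense artifacts of stranded
  library preparation);
* novel-transcript expression filtering — novel transcripts with
  RPKM < 0.5 that do not overlap a trusted reference mapping are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ParameterError
from .models import GenomicInterval, TranscriptionalUnit

DEFAULT_RATIO_THRESHOLD = 5.0
DEFAULT_MIN_OVERLAP_FRAC = 0.5
DEFAULT_RPKM_MIN = 0.5


def exonic_overlap_nt(a: TranscriptionalUnit, b: TranscriptionalUnit) -> int:
    """Total exon-over-exon overlap between two TUs, in nucleotides."""
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += ea.overlap_nt(eb)
    return total


@dataclass(frozen=True)
class OverlapPair:
    """An opposite-strand overlapping TU pair with its exonic read counts."""

    sense_id: str
    antisense_id: str
    exonic_overlap_nt: int
    count_sense: int
    count_antisense: int


def find_antisense_pairs(
    tus: Sequence[TranscriptionalUnit], read_counts: dict[str, int]
) -> list[OverlapPair]:
    """Enumerate opposite-strand TU pairs with exonic overlap.

    By convention the higher-count member is reported as the sense side.
    """
    for tu in tus:
        if tu.tu_id not in read_counts:
            raise ParameterError(f"missing read count for TU {tu.tu_id!r}")
    plus = [t for t in tus if t.strand == "+"]
    minus = [t for t in tus if t.strand == "-"]
    trees: dict[str, IntervalTree] = {}
    for i, t in enumerate(minus):
        trees.setdefault(t.scaffold_id, IntervalTree()).addi(
            t.interval.start, t.interval.end, i
        )
    pairs = []
    for a in plus:
        tree = trees.get(a.scaffold_id)
        if tree is None:
            continue
        for hit in sorted(tree[a.interval.start : a.interval.end], key=lambda h: h.data):
            b = minus[hit.data]
            ov = exonic_overlap_nt(a, b)
            if ov < 1:
                continue
            ca, cb = read_counts[a.tu_id], read_counts[b.tu_id]
            if ca >= cb:
                pairs.append(OverlapPair(a.tu_id, b.tu_id, ov, ca, cb))
            else:
                pairs.append(OverlapPair(b.tu_id, a.tu_id, ov, cb, ca))
    return pairs


def filter_antisense(
    tus: Sequence[TranscriptionalUnit],
    read_counts: dict[str, int],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> tuple[list[TranscriptionalUnit], list[TranscriptionalUnit], list[dict]]:
    """Discard the lower-expressing strand of overlapping antisense pairs.

    A pair qualifies when the exonic overlap covers at least
    ``min_overlap_frac`` of the lower-expressed transcript's exonic length.
    The lower-count member is discarded when the count ratio is at least
    ``ratio_threshold`` (a zero count makes the ratio infinite).  Decisions
    use the original counts for every pair, so a transcript discarded via one
    pair can never rescue another (and the filter is idempotent).
    """
    if ratio_threshold <= 1:
        raise ParameterError("ratio_threshold must be > 1")
    by_id = {t.tu_id: t for t in tus}
    discard: set[str] = set()
    report: list[dict] = []
    for pair in find_antisense_pairs(tus, read_counts):
        low = by_id[pair.antisense_id]
        if pair.exonic_overlap_nt < min_overlap_frac * low.exonic_length:
            continue
        if pair.count_sense == 0 and pair.count_antisense == 0:
            continue  # no expression difference to act on
        if pair.count_antisense == 0:
            ratio = float("inf")
        else:
            ratio = pair.count_sense / pair.count_antisense
        if ratio >= ratio_threshold:
            discard.add(pair.antisense_id)
            report.append(
                {
                    "discarded": pair.antisense_id,
                    "kept": pair.sense_id,
                    "count_kept": pair.count_sense,
                    "count_discarded": pair.count_antisense,
                    "ratio": ratio,
                    "overlap_nt": pair.exonic_overlap_nt,
                    "reason": "antisense",
                }
            )
    kept = [t for t in tus if t.tu_id not in discard]
    discarded = [t for t in tus if t.tu_id in discard]
    return kept, discarded, report


def filter_low_expression_novel(
    tus: Sequence[TranscriptionalUnit],
    reference_overlaps: set[str],
    rpkm_min: float = DEFAULT_RPKM_MIN,
) -> tuple[list[TranscriptionalUnit], list[TranscriptionalUnit]]:
    """Discard TUs with RPKM strictly below ``rpkm_min`` that do not overlap
    a trusted reference mapping."""
    kept, discarded = [], []
    for tu in tus:
        if tu.expression_rpkm < rpkm_min and tu.tu_id not in reference_overlaps:
            discarded.append(tu)
        else:
            kept.append(tu)
    return kept, discarded


def tus_overlapping(
    tus: Sequence[TranscriptionalUnit], reference: Iterable[GenomicInterval]
) -> set[str]:
    """IDs of TUs whose span overlaps any reference interval (strand-blind)."""
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.scaffold_id, IntervalTree()).addi(iv.start, iv.end)
    hits = set()
    for tu in tus:
        tree = trees.get(tu.scaffold_id)
        if tree is not None and tree.overlaps(tu.interval.start, tu.interval.end):
            hits.add(tu.tu_id)
    return hits
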