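"""Core domain objects.

Coordinate convention: every in-memory interval is 0-based, half-open
``[start, end)`` on a named scaffold.  Conversion to and from the 1-based
inclusive GTF convention happens in :mod:`tbone.io_formats` and nowhere else.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ValidationError

VALID_STRANDS = ("+", "-", ".")
NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval ``[start, end)`` on a scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_nt(self, other: "GenomicInterval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def sort_key(self):
        return (self.scaffold_id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold of an assembly, stored upper-case."""

    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"empty sequence for {self.scaffold_id}")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"illegal characters {sorted(bad)} in sequence {self.scaffold_id}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_exons(
    exons: Sequence[GenomicInterval], interval: GenomicInterval, label: str
) -> None:
    if not exons:
        raise ValidationError(f"{label}: no exons")
    prev_end = None
    for ex in exons:
        if ex.scaffold_id != interval.scaffold_id:
            raise ValidationError(f"{label}: exon on wrong scaffold {ex.scaffold_id}")
        if prev_end is not None and ex.start < prev_end:
            raise ValidationError(f"{label}: exons unsorted or overlapping")
        prev_end = ex.end
    if exons[0].start != interval.start or exons[-1].end != interval.end:
        raise ValidationError(
            f"{label}: exon span [{exons[0].start}, {exons[-1].end}) "
            f"does not match interval [{interval.start}, {interval.end})"
        )


@dataclass
class TranscriptionalUnit:
    """An assembled, possibly polycistronic, transcript.

    The exon list is sorted by start, non-overlapping, and tiles the interval
    ends exactly (first exon start == interval start, last exon end ==
    interval end).
    """

    tu_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    expression_rpkm: float = 0.0
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"TU {self.tu_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _check_exons(self.exons, self.interval, f"TU {self.tu_id}")
        if self.expression_rpkm < 0:
            raise ValidationError(f"TU {self.tu_id}: negative RPKM")

    @classmethod
    def from_exons(
        cls,
        tu_id: str,
        exons: Iterable[GenomicInterval],
        strand: str,
        expression_rpkm: float = 0.0,
        source_tag: str = "",
    ) -> "TranscriptionalUnit":
        exons = sorted(exons, key=lambda e: e.start)
        interval = GenomicInterval(
            exons[0].scaffold_id, exons[0].start, exons[-1].end, strand
        )
        return cls(tu_id, interval, list(exons), expression_rpkm, source_tag)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def scaffold_id(self) -> str:
        return self.interval.scaffold_id


class RepeatMask:
    """A merged, strand-agnostic set of repeat intervals.

    Intervals are normalized on construction: sorted and merged so no two
    stored intervals overlap or touch.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_scaffold.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for scaf, ivs in by_scaffold.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[scaf] = merged

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = []
        for scaf in sorted(self._merged):
            for s, e in self._merged[scaf]:
                out.append(GenomicInterval(scaf, s, e, "."))
        return out

    def coverage_nt(self, scaffold_id: str, start: int, end: int) -> int:
        """Number of masked bases within ``[start, end)``."""
        total = 0
        ivs = self._merged.get(scaffold_id, [])
        starts = [s for s, _ in ivs]
        i = max(0, bisect.bisect_right(starts, start) - 1)
        for s, e in ivs[i:]:
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total

    def total_masked(self) -> int:
        return sum(e - s for ivs in self._merged.values() for s, e in ivs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._merged.values())


@dataclass(frozen=True)
class OrfRecord:
    """A called open reading frame, in mature-transcript coordinates.

    ``start``/``end`` are 0-based half-open offsets in the spliced transcript
    (stop codon included in the span for complete ORFs); ``protein`` excludes
    the stop symbol.
    """

    start: int
    end: int
    frame: int
    protein: str
    complete: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValidationError("ORF span not divisible by 3")
        if self.frame not in (0, 1, 2):
            raise ValidationError(f"invalid frame {self.frame}")
        expected = (self.end - self.start) // 3 - (1 if self.complete else 0)
        if len(self.protein) != expected:
            raise ValidationError(
                f"protein length {len(self.protein)} != expected {expected}"
            )


@dataclass
class GeneModel:
    """A mature-mRNA-level record produced by cutting a transcriptional unit."""

    gene_id: str
    parent_tu_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    has_sl_5p: bool = False
    has_polya_3p: bool = False
    sl_summit: Optional[int] = None
    polya_summit: Optional[int] = None
    classification: str = "NO_SL"
    orf: Optional[OrfRecord] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _check_exons(self.exons, self.interval, f"gene {self.gene_id}")
        if self.classification not in ("SL_SINGLE", "SL_MULTIPLE_PARENT", "NO_SL"):
            raise ValidationError(f"invalid classification {self.classification}")

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def scaffold_id(self) -> str:
        return self.interval.scaffold_id

    @property
    def intron_lengths(self) -> list[int]:
        return [
            b.start - a.end for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class TaggedRead:
    """A read after evidence detection.

    ``trimmed_prefix_len`` holds the number of trimmed bases: the spliced
    leader prefix for SL evidence, the poly(A) tail suffix for POLYA evidence.
    """

    read_id: str
    sequence: str
    trimmed_prefix_len: int = 0
    evidence_kind: str = "NONE"

    def __post_init__(self) -> None:
        if self.evidence_kind not in ("SL", "POLYA", "NONE"):
            raise ValidationError(f"invalid evidence kind {self.evidence_kind}")
        if self.evidence_kind == "SL" and self.trimmed_prefix_len <= 0:
            raise ValidationError("SL evidence requires a trimmed prefix")


@dataclass(frozen=True)
class EvidencePeak:
    """A clustered end-signal peak (SL 5' ends or poly(A) 3' ends)."""

    kind: str
    interval: GenomicInterval
    summit: int
    total_count: int

    def __post_init__(self) -> None:
        if self.kind not in ("SL", "POLYA"):
            raise ValidationError(f"invalid peak kind {self.kind}")
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside peak interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.total_count < 1:
            raise ValidationError("peak total_count must be >= 1")


class EndSignalTrack:
    """Strand-specific per-base counts of read end positions."""

    def __init__(self, kind: str):
        if kind not in ("SL", "POLYA"):
            raise ValidationError(f"invalid track kind {kind}")
        self.kind = kind
        # (scaffold, strand) -> {position: count}
        self.counts: dict[tuple[str, str], dict[int, int]] = {}

    def add(self, scaffold_id: str, strand: str, position: int, count: int = 1) -> None:
        if strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {strand!r} in track")
        if position < 0:
            raise ValidationError(f"negative position {position}")
        key = (scaffold_id, strand)
        bucket = self.counts.setdefault(key, {})
        bucket[position] = bucket.get(position, 0) + count

    def total(self) -> int:
        return sum(c for bucket in self.counts.values() for c in bucket.values())

    def items(self):
        for key in sorted(self.counts):
            yield key, self.counts[key]


@dataclass(frozen=True)
class DupBlock:
    """A pair of non-self duplicated genomic intervals."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    orientation: str
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValidationError(f"invalid orientation {self.orientation}")
        if self.interval_a.sort_key() > self.interval_b.sort_key():
            raise ValidationError("dup block intervals not canonically ordered")
        if self.interval_a.overlaps(self.interval_b):
            raise ValidationError("dup block is a self-hit (overlapping intervals)")
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"identity {self.identity} outside [0, 1]")
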