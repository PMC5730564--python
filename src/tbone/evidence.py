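"""Spliced-leader and poly(A) evidence extraction and peak calling.

Trans-spliced mRNAs begin with a short spliced-leader (SL) sequence donated
by an SL RNA; a sequencing read that starts with a 3' suffix of the leader
pinpoints the trans-splice acceptor site at its first post-leader base.
Symmetrically, 3'-end protocol reads (T-fill style) end immediately upstream
of the poly(A) tail and pinpoint cleavage sites.  This module tags and trims
such reads, piles mapped end positions into strand-specific tracks, and
groups track positions into evidence peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .errors import ParameterError, ValidationError
from .models import EndSignalTrack, EvidencePeak, GenomicInterval, TaggedRead

MIN_REMAINING_READ_LEN = 20


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a FASTQ file (via Biopython)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Read tagging


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def detect_and_trim_sl(
    reads: Iterable[tuple[str, str]],
    sl_leader: str,
    min_match: int = 10,
    max_mismatch: int = 1,
) -> Iterator[TaggedRead]:
    """Tag reads whose prefix matches a 3' suffix of the spliced leader.

    The longest leader suffix of length >= ``min_match`` matching the read
    prefix with <= ``max_mismatch`` mismatches is trimmed.  Reads shorter than
    20 nt after trimming are not usable as evidence and come back as NONE.
    """
    sl_leader = sl_leader.upper()
    if not sl_leader:
        raise ParameterError("empty SL leader sequence")
    if not (1 <= min_match <= len(sl_leader)):
        raise ParameterError(
            f"min_match must be in [1, leader length]; got {min_match}"
        )
    for read_id, seq in reads:
        seq = seq.upper()
        best = 0
        max_len = min(len(sl_leader), len(seq))
        for length in range(max_len, min_match - 1, -1):
            if _mismatches(sl_leader[-length:], seq[:length], max_mismatch) <= max_mismatch:
                best = length
                break
        if best and len(seq) - best >= MIN_REMAINING_READ_LEN:
            yield TaggedRead(read_id, seq[best:], best, "SL")
        else:
            yield TaggedRead(read_id, seq, 0, "NONE")


def detect_polya_tail(
    reads: Iterable[tuple[str, str]],
    min_a_run: int = 5,
    max_non_a: int = 1,
    assume_tfill: bool = False,
) -> Iterator[TaggedRead]:
    """Trim trailing poly(A) runs and tag 3'-end evidence reads.

    A trailing run of A's, allowing up to ``max_non_a`` non-A interruptions,
    is removed when it contains at least ``min_a_run`` A's.  With
    ``assume_tfill=True`` every read is tagged POLYA even without a tail
    (T-fill protocol reads end at the cleavage site by construction).
    """
    if min_a_run < 5:
        raise ParameterError(f"min_a_run must be >= 5; got {min_a_run}")
    for read_id, seq in reads:
        seq = seq.upper()
        i = len(seq) - 1
        non_a = 0
        while i >= 0:
            if seq[i] == "A":
                i -= 1
            else:
                non_a += 1
                if non_a > max_non_a:
                    break
                i -= 1
        j = i + 1
        while j < len(seq) and seq[j] != "A":  # tail must begin with an A
            j += 1
        n_a = seq[j:].count("A")
        if n_a >= min_a_run and len(seq) - (len(seq) - j) >= 1:
            yield TaggedRead(read_id, seq[:j], len(seq) - j, "POLYA")
        elif assume_tfill:
            yield TaggedRead(read_id, seq, 0, "POLYA")
        else:
            yield TaggedRead(read_id, seq, 0, "NONE")


# ---------------------------------------------------------------------------
# Placement ingestion and pileup


def pileup_end_positions(
    placements: Iterable[tuple[str, str, int]],
    kind: str,
    genome: Optional[dict[str, str]] = None,
) -> EndSignalTrack:
    """Accumulate mapped biological end positions into a signal track.

    Each placement is ``(scaffold, strand, position)`` where the position is
    the first transcribed base (SL) or the last transcribed base before the
    tail (POLYA), 0-based.
    """
    track = EndSignalTrack(kind)
    for scaf, strand, pos in placements:
        if genome is not None:
            if scaf not in genome:
                raise ValidationError(f"placement on unknown scaffold {scaf!r}")
            if not (0 <= pos < len(genome[scaf])):
                raise ValidationError(
                    f"placement position {pos} outside scaffold {scaf}"
                )
        track.add(scaf, strand, pos)
    return track


def placements_from_bed(path: str) -> Iterator[tuple[str, str, int]]:
    """Read end placements from BED6: the interval start is the end position."""
    from .io_formats import read_bed

    for iv in read_bed(path):
        if iv.strand not in ("+", "-"):
            raise ValidationError(f"unstranded placement on {iv.scaffold_id}")
        yield iv.scaffold_id, iv.strand, iv.start


def placements_from_sam(path: str, kind: str) -> Iterator[tuple[str, str, int]]:
    """Derive end placements from a SAM/BAM file of mapped, trimmed reads.

    Soft-clipped bases are ignored: positions come from aligned bases only.
    For SL evidence the biological end is the alignment start on ``+`` and
    the alignment end - 1 on ``-``; for POLYA it is the opposite end.
    """
    import pysam

    if kind not in ("SL", "POLYA"):
        raise ParameterError(f"invalid placement kind {kind}")
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            left = aln.reference_start
            right = aln.reference_end - 1
            if kind == "SL":
                pos = left if strand == "+" else right
            else:
                pos = right if strand == "+" else left
            yield aln.reference_name, strand, pos


# ---------------------------------------------------------------------------
# Peak calling


def call_peaks(
    track: EndSignalTrack, min_site_count: int = 5, merge_distance: int = 10
) -> list[EvidencePeak]:
    """Group nearby signal positions into peaks.

    Per (scaffold, strand), positions with signal are grouped into runs where
    consecutive positions are <= ``merge_distance`` apart; a run becomes a
    peak iff its total count >= ``min_site_count``.  The summit is the
    highest-count position; ties break toward the transcript 5' direction
    (genomic left on ``+``, right on ``-``).
    """
    if min_site_count < 1:
        raise ParameterError("min_site_count must be >= 1")
    if merge_distance < 0:
        raise ParameterError("merge_distance must be >= 0")
    peaks: list[EvidencePeak] = []
    for (scaf, strand), bucket in track.items():
        positions = sorted(bucket)
        group: list[int] = []

        def flush(group: list[int]) -> None:
            total = sum(bucket[p] for p in group)
            if total < min_site_count:
                return
            best = max(bucket[p] for p in group)
            candidates = [p for p in group if bucket[p] == best]
            summit = min(candidates) if strand == "+" else max(candidates)
            peaks.append(
                EvidencePeak(
                    kind=track.kind,
                    interval=GenomicInterval(scaf, group[0], group[-1] + 1, strand),
                    summit=summit,
                    total_count=total,
                )
            )

        for pos in positions:
            if group and pos - group[-1] > merge_distance:
                flush(group)
                group = []
            group.append(pos)
        if group:
            flush(group)
    peaks.sort(key=lambda p: (p.interval.sort_key(), p.kind))
    return peaks


def compute_rpkm(
    read_count: int, transcript_length_nt: int, total_mapped_reads: int
) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length_nt < 1 or total_mapped_reads < 1:
        raise ParameterError("transcript length and total mapped reads must be >= 1")
    return read_count * 1e9 / (transcript_length_nt * total_mapped_reads)


@dataclass
class TaggingReport:
    """Counts from a read-tagging pass."""

    n_reads: int = 0
    n_tagged: int = 0

    def observe(self, read: TaggedRead) -> TaggedRead:
        self.n_reads += 1
        if read.evidence_kind != "NONE":
            self.n_tagged += 1
        return read
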