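"""Longest-ORF calling and ORF/poly(A)-aware merging of split gene models.

Gene models that straddle an assembly gap or a repeat often come apart into
an upstream fragment carrying the ORF (but no poly(A) site) and a downstream
fragment carrying the poly(A) site (but no ORF).  Such adjacent fragments are
re-joined when the genomic gap between them is at most 10 kb and the spanned
region is repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ValidationError
from .models import GeneModel, GenomicInterval, OrfRecord, RepeatMask, revcomp

DEFAULT_MIN_AA = 100
DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_REPEAT_FRAC = 0.5

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)


def translate_cds(seq: str) -> str:
    """Translate a CDS (stop codon, if present, is dropped; unknown codons
    become 'X')."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def find_longest_orf(transcript_seq: str, min_aa: int = DEFAULT_MIN_AA) -> Optional[OrfRecord]:
    """Longest complete ORF (ATG to first in-frame stop) in 3 forward frames.

    Returns the longest candidate whose protein is at least ``min_aa``
    residues; ties break to the 5'-most start.  The transcript is assumed to
    be in mature 5'->3' orientation, so reverse frames are never scanned.
    """
    seq = transcript_seq.upper()
    best: Optional[OrfRecord] = None
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                n_aa = (i - start) // 3
                if n_aa >= min_aa and (
                    best is None
                    or n_aa > len(best.protein)
                    or (n_aa == len(best.protein) and start < best.start)
                ):
                    best = OrfRecord(
                        start=start,
                        end=i + 3,
                        frame=frame,
                        protein=translate_cds(seq[start : i + 3]),
                        complete=True,
                    )
                start = None
    return best


def transcript_sequence(gene: GeneModel, genome: dict[str, str]) -> str:
    """Spliced mature transcript sequence in 5'->3' orientation."""
    chrom = genome[gene.scaffold_id]
    seq = "".join(chrom[e.start : e.end] for e in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


def call_orfs(
    genes: Sequence[GeneModel], genome: dict[str, str], min_aa: int = DEFAULT_MIN_AA
) -> None:
    """Annotate each gene in place with its longest ORF (or None)."""
    for g in genes:
        g.orf = find_longest_orf(transcript_sequence(g, genome), min_aa=min_aa)


@dataclass
class MergeEvent:
    upstream_id: str
    downstream_id: str
    gap_nt: int
    repeat_frac: float
    orf_before: Optional[OrfRecord]
    orf_after: Optional[OrfRecord]


def _gap_interval(a: GeneModel, b: GeneModel) -> tuple[int, int]:
    """Genomic gap between the facing ends of upstream a and downstream b."""
    if a.strand == "+":
        return a.interval.end, b.interval.start
    return b.interval.end, a.interval.start


def merge_split_transcripts(
    genes: Sequence[GeneModel],
    repeat_mask: RepeatMask,
    max_gap: int = DEFAULT_MAX_GAP,
    min_repeat_frac: float = DEFAULT_MIN_REPEAT_FRAC,
    genome: Optional[dict[str, str]] = None,
    min_aa: int = DEFAULT_MIN_AA,
) -> tuple[list[GeneModel], list[MergeEvent]]:
    """Merge ORF-bearing fragments with their downstream poly(A) fragments.

    For each adjacent same-strand pair (A upstream, B downstream in transcript
    orientation), merge iff A has an ORF but no poly(A) site, B has a poly(A)
    site but no ORF, the genomic gap is <= ``max_gap``, and the repeat mask
    covers >= ``min_repeat_frac`` of the gap (an empty gap counts as fully
    covered).  Merging is single-pass 5'->3'; a merged model is re-examined
    against the next fragment only if the conditions hold again.  When a
    genome is supplied the merged model's ORF is re-called.
    """
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault((g.scaffold_id, g.strand), []).append(g)

    merged_all: list[GeneModel] = []
    events: list[MergeEvent] = []
    for (scaf, strand), group in sorted(by_group.items()):
        group = sorted(group, key=lambda g: g.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.end > b.interval.start:
                raise ValidationError(
                    f"overlapping gene models {a.gene_id} / {b.gene_id} on "
                    f"{scaf}{strand}"
                )
        if strand == "-":
            group = group[::-1]  # transcript orientation

        out: list[GeneModel] = []
        i = 0
        while i < len(group):
            a = group[i]
            while i + 1 < len(group):
                b = group[i + 1]
                if not (
                    a.orf is not None
                    and not a.has_polya_3p
                    and b.orf is None
                    and b.has_polya_3p
                ):
                    break
                gap_start, gap_end = _gap_interval(a, b)
                gap = gap_end - gap_start
                if gap > max_gap:
                    break
                if gap > 0:
                    frac = repeat_mask.coverage_nt(scaf, gap_start, gap_end) / gap
                else:
                    frac = 1.0
                if frac < min_repeat_frac:
                    break
                merged = _merge_pair(a, b)
                if genome is not None:
                    merged.orf = find_longest_orf(
                        transcript_sequence(merged, genome), min_aa=min_aa
                    )
                else:
                    merged.orf = a.orf
                events.append(
                    MergeEvent(
                        upstream_id=a.gene_id,
                        downstream_id=b.gene_id,
                        gap_nt=gap,
                        repeat_frac=frac,
                        orf_before=a.orf,
                        orf_after=merged.orf,
                    )
                )
                a = merged
                i += 1
            out.append(a)
            i += 1
        merged_all.extend(out)
    merged_all.sort(key=lambda g: (g.interval.sort_key(), g.gene_id))
    return merged_all, events


def _merge_pair(a: GeneModel, b: GeneModel) -> GeneModel:
    """Union of two gene models; the inter-model gap becomes an intron."""
    exons = sorted(a.exons + b.exons, key=lambda e: e.start)
    interval = GenomicInterval(
        a.scaffold_id, exons[0].start, exons[-1].end, a.strand
    )
    up, down = (a, b)
    return GeneModel(
        gene_id=up.gene_id,
        parent_tu_id=up.parent_tu_id,
        interval=interval,
        exons=exons,
        has_sl_5p=up.has_sl_5p,
        has_polya_3p=down.has_polya_3p,
        sl_summit=up.sl_summit,
        polya_summit=down.polya_summit,
        classification=up.classification,
        orf=None,
        notes=(up.notes + ("," if up.notes else "") + f"merged:{down.gene_id}"),
    )
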