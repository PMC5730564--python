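"""Cutting transcriptional units into mature-mRNA gene models.

An assembled transcriptional unit (TU) may be a polycistronic precursor:
several genes separated by trans-splice acceptor sites.  Given SL and poly(A)
evidence peaks assigned to a TU, the cutter partitions the TU at SL summits
(each summit is the first transcribed base of a mature mRNA) and closes each
gene at the strongest poly(A) summit within its segment (the last transcribed
base before the tail).

All cutting logic runs in *oriented* coordinates: positions on a minus-strand
TU are reflected (``p -> -(p + 1)``) so transcript 5'->3' is always
increasing.  This makes cutting commute with strand reflection by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError
from .models import EvidencePeak, GeneModel, GenomicInterval, TranscriptionalUnit

DEFAULT_END_SLACK = 50
DEFAULT_MIN_GENE_LEN = 100


@dataclass
class CutParams:
    """Tunable cutting parameters.

    end_slack: evidence slightly outside an assembled TU end extends the
        model rather than being ignored (assemblers under-assemble ends).
    min_gene_len: genes with clipped exonic length below this are dropped;
        a 5' leader segment must exceed it to be emitted.
    """

    end_slack: int = DEFAULT_END_SLACK
    min_gene_len: int = DEFAULT_MIN_GENE_LEN


@dataclass
class PeakAssignment:
    by_tu: dict[str, tuple[list[EvidencePeak], list[EvidencePeak]]] = field(
        default_factory=dict
    )
    # peaks whose summit fell inside more than one TU, with the TU ids hit
    multi_assigned: list[tuple[EvidencePeak, list[str]]] = field(default_factory=list)


def assign_peaks_to_tu(
    tus: Sequence[TranscriptionalUnit],
    peaks: Sequence[EvidencePeak],
    end_slack: int = DEFAULT_END_SLACK,
) -> PeakAssignment:
    """Assign each peak to every TU whose slack-padded span contains its summit
    on the matching strand."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tu in tus:
        key = (tu.scaffold_id, tu.strand)
        tree = trees.setdefault(key, IntervalTree())
        tree.addi(
            max(0, tu.interval.start - end_slack), tu.interval.end + end_slack, tu.tu_id
        )
    out = PeakAssignment(by_tu={tu.tu_id: ([], []) for tu in tus})
    for peak in peaks:
        key = (peak.interval.scaffold_id, peak.interval.strand)
        if key not in trees:
            continue
        hits = sorted(iv.data for iv in trees[key][peak.summit])
        for tu_id in hits:
            sl, polya = out.by_tu[tu_id]
            (sl if peak.kind == "SL" else polya).append(peak)
        if len(hits) > 1:
            out.multi_assigned.append((peak, hits))
    for sl, polya in out.by_tu.values():
        sl.sort(key=lambda p: p.summit)
        polya.sort(key=lambda p: p.summit)
    return out


# ---------------------------------------------------------------------------
# Oriented-coordinate helpers (minus strand is reflected)


def _orient(pos: int, strand: str) -> int:
    return pos if strand == "+" else -(pos + 1)


def _unorient(pos: int, strand: str) -> int:
    return pos if strand == "+" else -(pos + 1)


def _orient_interval(start: int, end: int, strand: str) -> tuple[int, int]:
    return (start, end) if strand == "+" else (-end, -start)


def _clip_exons(
    exons: list[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    """Intersect oriented exons with [start, end); extend the terminal exons
    when the gene span reaches beyond the exon space (evidence extensions)."""
    clipped = [
        (max(s, start), min(e, end)) for s, e in exons if max(s, start) < min(e, end)
    ]
    if not clipped:
        return []
    if start < clipped[0][0]:
        clipped[0] = (start, clipped[0][1])
    if end > clipped[-1][1]:
        clipped[-1] = (clipped[-1][0], end)
    return clipped


def _snap_into_exons(
    pos: int, exons: list[tuple[int, int]], direction: str
) -> tuple[int, bool]:
    """Snap an intronic position to the nearest exonic base.

    direction '3prime' snaps forward in transcript orientation (SL summits),
    '5prime' snaps backward (poly(A) summits).  Positions outside the exon
    span are left untouched (they extend the model).
    """
    if pos < exons[0][0] or pos >= exons[-1][1]:
        return pos, False
    for s, e in exons:
        if s <= pos < e:
            return pos, False
    if direction == "3prime":
        for s, e in exons:
            if s > pos:
                return s, True
    else:
        best = None
        for s, e in exons:
            if e - 1 < pos:
                best = e - 1
        if best is not None:
            return best, True
    return pos, False  # pragma: no cover - unreachable given bounds check


def cut_tu(
    tu: TranscriptionalUnit,
    sl_peaks: Sequence[EvidencePeak],
    polya_peaks: Sequence[EvidencePeak],
    params: Optional[CutParams] = None,
) -> list[GeneModel]:
    """Partition one TU at its SL summits and close genes at poly(A) summits.

    With SL summits ``s1 < ... < sk`` (transcript orientation), gene *i*
    starts at ``s_i`` and ends at the strongest poly(A) summit strictly
    between ``s_i`` and ``s_{i+1}`` (TU 3' end for the last gene); without
    poly(A) evidence the segment runs to the next summit (or TU end) and is
    flagged accordingly.  A 5' leader segment longer than ``min_gene_len`` is
    emitted without SL evidence.  With no SL summit at all the TU becomes a
    single NO_SL gene, trimmed at its strongest poly(A) summit if one exists.
    """
    params = params or CutParams()
    strand = tu.strand
    for p in list(sl_peaks) + list(polya_peaks):
        if p.interval.strand != strand or p.interval.scaffold_id != tu.scaffold_id:
            raise ValidationError(
                f"peak on {p.interval.scaffold_id}{p.interval.strand} assigned to "
                f"TU {tu.tu_id} on {tu.scaffold_id}{strand} (assignment bug)"
            )

    exons = sorted(_orient_interval(e.start, e.end, strand) for e in tu.exons)
    span_start, span_end = exons[0][0], exons[-1][1]

    sl_summits: list[int] = []
    snapped_sl = set()
    for p in sl_peaks:
        o = _orient(p.summit, strand)
        if o >= span_end:  # SL at/after the 3' end cannot start a gene
            continue
        o2, snapped = _snap_into_exons(o, exons, "3prime")
        if snapped:
            snapped_sl.add(o2)
        sl_summits.append(o2)
    sl_summits = sorted(set(sl_summits))

    polya: list[tuple[int, int]] = []  # (oriented summit, total_count)
    snapped_pa = set()
    for p in polya_peaks:
        o = _orient(p.summit, strand)
        o2, snapped = _snap_into_exons(o, exons, "5prime")
        if snapped:
            snapped_pa.add(o2)
        polya.append((o2, p.total_count))

    def best_polya(lo: int, hi: Optional[int]) -> Optional[int]:
        """Strongest poly(A) summit with lo < summit (< hi); ties 5'-most."""
        cands = [
            (count, pos)
            for pos, count in polya
            if pos > lo and (hi is None or pos < hi)
        ]
        if not cands:
            return None
        best_count = max(c for c, _ in cands)
        return min(pos for c, pos in cands if c == best_count)

    segments: list[dict] = []  # oriented gene drafts
    if not sl_summits:
        p = best_polya(span_start - 1, None)
        seg = {"start": span_start, "sl": None, "polya": p}
        seg["end"] = (p + 1) if p is not None else span_end
        segments.append(seg)
    else:
        s1 = sl_summits[0]
        leader_exons = _clip_exons(exons, span_start, s1) if s1 > span_start else []
        leader_len = sum(e - s for s, e in leader_exons)
        if leader_len > params.min_gene_len:
            p = best_polya(span_start - 1, s1)
            segments.append(
                {
                    "start": span_start,
                    "end": (p + 1) if p is not None else s1,
                    "sl": None,
                    "polya": p,
                }
            )
        for i, s in enumerate(sl_summits):
            nxt = sl_summits[i + 1] if i + 1 < len(sl_summits) else None
            p = best_polya(s, nxt)
            if p is not None:
                end = p + 1
            else:
                end = nxt if nxt is not None else span_end
            segments.append({"start": s, "end": end, "sl": s, "polya": p})

    genes: list[GeneModel] = []
    n = 0
    for seg in segments:
        gexons = _clip_exons(exons, seg["start"], seg["end"])
        glen = sum(e - s for s, e in gexons)
        if not gexons or glen < params.min_gene_len:
            continue
        n += 1
        notes = []
        if seg["sl"] in snapped_sl:
            notes.append("sl_snapped")
        if seg["polya"] in snapped_pa:
            notes.append("polya_snapped")
        if seg["start"] < span_start or gexons[0][0] < span_start:
            notes.append("5p_extended")
        if gexons[-1][1] > span_end:
            notes.append("3p_extended")
        # back to genomic coordinates
        gen_exons = sorted(
            _orient_interval(s, e, strand) if strand == "+" else (-e, -s)
            for s, e in gexons
        )
        ivs = [
            GenomicInterval(tu.scaffold_id, s, e, strand) for s, e in gen_exons
        ]
        genes.append(
            GeneModel(
                gene_id=f"{tu.tu_id}.g{n}",
                parent_tu_id=tu.tu_id,
                interval=GenomicInterval(
                    tu.scaffold_id, gen_exons[0][0], gen_exons[-1][1], strand
                ),
                exons=ivs,
                has_sl_5p=seg["sl"] is not None,
                has_polya_3p=seg["polya"] is not None,
                sl_summit=(
                    _unorient(seg["sl"], strand) if seg["sl"] is not None else None
                ),
                polya_summit=(
                    _unorient(seg["polya"], strand) if seg["polya"] is not None else None
                ),
                notes=",".join(notes),
            )
        )
    return genes


def classify_genes(genes: Sequence[GeneModel]) -> tuple[list[GeneModel], dict]:
    """Assign SL classifications per parent TU and tabulate summary counts.

    A parent with one SL summit yields SL_SINGLE genes; with several, all its
    SL genes are SL_MULTIPLE_PARENT (the parent is counted once under
    "multiple").  Genes without SL evidence are NO_SL.
    """
    by_parent: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_parent.setdefault(g.parent_tu_id, []).append(g)

    out: list[GeneModel] = []
    n_single = n_multi = n_none = 0
    for parent in sorted(by_parent):
        children = by_parent[parent]
        n_sl = sum(1 for g in children if g.has_sl_5p)
        if n_sl == 0:
            n_none += 1
        elif n_sl == 1:
            n_single += 1
        else:
            n_multi += 1
        for g in children:
            if not g.has_sl_5p:
                g.classification = "NO_SL"
            elif n_sl == 1:
                g.classification = "SL_SINGLE"
            else:
                g.classification = "SL_MULTIPLE_PARENT"
            out.append(g)

    n_parents = len(by_parent)
    n_genes = len(out)
    n_polya = sum(1 for g in out if g.has_polya_3p)

    def pct(x: int, total: int) -> float:
        return 100.0 * x / total if total else 0.0

    summary = {
        "n_parents": n_parents,
        "n_genes": n_genes,
        "n_single_sl": n_single,
        "n_multiple_sl": n_multi,
        "n_no_sl": n_none,
        "pct_single_sl": pct(n_single, n_parents),
        "pct_multiple_sl": pct(n_multi, n_parents),
        "pct_no_sl": pct(n_none, n_parents),
        "n_polya_genes": n_polya,
        "pct_polya_genes": pct(n_polya, n_genes),
    }
    return out, summary


def cut_all(
    tus: Sequence[TranscriptionalUnit],
    peaks: Sequence[EvidencePeak],
    params: Optional[CutParams] = None,
) -> tuple[list[GeneModel], dict, PeakAssignment]:
    """Assign peaks, cut every TU, and classify the resulting genes."""
    params = params or CutParams()
    assignment = assign_peaks_to_tu(tus, peaks, end_slack=params.end_slack)
    genes: list[GeneModel] = []
    for tu in tus:
        sl, polya = assignment.by_tu[tu.tu_id]
        genes.extend(cut_tu(tu, sl, polya, params))
    genes, summary = classify_genes(genes)
    genes.sort(key=lambda g: (g.interval.sort_key(), g.gene_id))
    return genes, summary, assignment
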