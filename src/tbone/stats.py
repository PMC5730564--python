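"""Assembly-level summary statistics over transcriptional units and genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .models import GeneModel, TranscriptionalUnit
from .redundancy import ClusterAssignment


@dataclass
class AssemblySummary:
    n_transcriptional_units: int = 0
    n_genes: int = 0
    total_length_nt: int = 0
    n_nonredundant: int = 0
    nonredundant_length_nt: int = 0
    shortest_transcript_nt: int = 0
    longest_transcript_nt: int = 0
    average_transcript_nt: float = 0.0
    n_single_sl: int = 0
    pct_single_sl: float = 0.0
    n_multiple_sl: int = 0
    pct_multiple_sl: float = 0.0
    n_polya: int = 0
    pct_polya: float = 0.0
    average_gene_span_nt: float = 0.0
    average_introns_per_gene: float = 0.0
    average_intron_length_nt: float = 0.0

    def to_rows(self) -> list[tuple[str, str]]:
        fmt = lambda x: (f"{x:.2f}" if isinstance(x, float) else str(x))  # noqa: E731
        return [
            ("transcriptional_units", fmt(self.n_transcriptional_units)),
            ("genes", fmt(self.n_genes)),
            ("total_length_nt", fmt(self.total_length_nt)),
            ("nonredundant_transcripts", fmt(self.n_nonredundant)),
            ("nonredundant_length_nt", fmt(self.nonredundant_length_nt)),
            ("shortest_transcript_nt", fmt(self.shortest_transcript_nt)),
            ("longest_transcript_nt", fmt(self.longest_transcript_nt)),
            ("average_transcript_nt", fmt(self.average_transcript_nt)),
            ("single_trans_splice_site", f"{self.n_single_sl} ({self.pct_single_sl:.2f}%)"),
            (
                "multiple_trans_splice_sites",
                f"{self.n_multiple_sl} ({self.pct_multiple_sl:.2f}%)",
            ),
            ("defined_polya_site", f"{self.n_polya} ({self.pct_polya:.2f}%)"),
            ("average_gene_span_nt", fmt(self.average_gene_span_nt)),
            ("average_introns_per_gene", fmt(self.average_introns_per_gene)),
            ("average_intron_length_nt", fmt(self.average_intron_length_nt)),
        ]

    def to_tsv(self, path: str, provenance: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"#{provenance}\n")
            for key, value in self.to_rows():
                fh.write(f"{key}\t{value}\n")

    def to_text(self) -> str:
        width = max(len(k) for k, _ in self.to_rows())
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in self.to_rows())


def summarize(
    genes: Sequence[GeneModel],
    tus: Sequence[TranscriptionalUnit],
    clusters: Optional[ClusterAssignment] = None,
) -> AssemblySummary:
    """Tabulate assembly-level statistics from gene and TU records alone.

    Trans-splice-site counts are per parent TU (a parent with several SL
    summits counts once under "multiple"); the poly(A) percentage is over
    genes.  Transcript lengths are spliced (exonic) lengths.
    """
    if not genes:
        warnings.warn("no genes to summarize; emitting all-zero summary", stacklevel=2)
        return AssemblySummary(n_transcriptional_units=len(tus))

    by_parent: dict[str, int] = {}
    for g in genes:
        by_parent[g.parent_tu_id] = by_parent.get(g.parent_tu_id, 0) + (
            1 if g.has_sl_5p else 0
        )
    n_single = sum(1 for v in by_parent.values() if v == 1)
    n_multi = sum(1 for v in by_parent.values() if v >= 2)
    n_parents = len(by_parent)

    lengths = [g.exonic_length for g in genes]
    spans = [g.interval.length for g in genes]
    intron_lens = [il for g in genes for il in g.intron_lengths]
    n_polya = sum(1 for g in genes if g.has_polya_3p)

    n_nr = 0
    nr_len = 0
    if clusters is not None:
        gene_len = {g.gene_id: g.exonic_length for g in genes}
        reps = {rep for rep, _ in clusters.assignment.values()}
        n_nr = len(reps)
        nr_len = sum(gene_len.get(r, 0) for r in reps)

    def pct(x: int, total: int) -> float:
        return 100.0 * x / total if total else 0.0

    return AssemblySummary(
        n_transcriptional_units=len(tus),
        n_genes=len(genes),
        total_length_nt=sum(lengths),
        n_nonredundant=n_nr,
        nonredundant_length_nt=nr_len,
        shortest_transcript_nt=min(lengths),
        longest_transcript_nt=max(lengths),
        average_transcript_nt=sum(lengths) / len(lengths),
        n_single_sl=n_single,
        pct_single_sl=pct(n_single, n_parents),
        n_multiple_sl=n_multi,
        pct_multiple_sl=pct(n_multi, n_parents),
        n_polya=n_polya,
        pct_polya=pct(n_polya, len(genes)),
        average_gene_span_nt=sum(spans) / len(spans),
        average_introns_per_gene=len(intron_lens) / len(genes),
        average_intron_length_nt=(
            sum(intron_lens) / len(intron_lens) if intron_lens else 0.0
        ),
    )
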