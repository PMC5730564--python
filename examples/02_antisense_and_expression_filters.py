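"""Discard antisense artifacts and weakly expressed novel transcripts.

Stranded library preparation leaks a small fraction of reads onto the
opposite strand, so assemblers emit spurious antisense models.  Where
opposite-strand transcripts share exonic coordinates, the lower-expressing
strand is discarded when the read-count difference is at least fivefold.
Novel transcripts below 0.5 RPKM without reference support are dropped too.
"""

from tbone import SimulationConfig, filter_antisense, filter_low_expression_novel, simulate

sim = simulate(SimulationConfig(seed=7, n_tus=30, antisense_fraction=0.3))
kept, discarded, report = filter_antisense(sim.tus, sim.read_counts)

print(f"TUs in:               {len(sim.tus)}")
print(f"antisense discarded:  {len(discarded)}")
for row in report[:3]:
    print(
        f"  {row['discarded']} dropped vs {row['kept']} "
        f"(counts {row['count_discarded']} vs {row['count_kept']}, "
        f"ratio {row['ratio']:.1f})"
    )
planted = {r["antisense_id"] for r in sim.truth.antisense_pairs}
print(f"planted antisense recovered: {len(planted & {t.tu_id for t in discarded})}/{len(planted)}")

kept2, low = filter_low_expression_novel(kept, reference_overlaps=set(), rpkm_min=0.5)
print(f"low-expression novel discarded: {len(low)}; TUs kept: {len(kept2)}")
# Each dropped antisense TU is the planted lower-expressing strand of an
# overlapping pair at a count ratio >= 5.
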