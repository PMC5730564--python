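"""TBONE cutting: peak assignment, partitioning, classification."""

import pytest

from tbone.cutting import CutParams, assign_peaks_to_tu, classify_genes, cut_all, cut_tu
from tbone.errors import ValidationError
from tbone.evidence import call_peaks, pileup_end_positions
from tbone.models import EvidencePeak, GenomicInterval

from conftest import make_tu


def peak(kind, scaffold, strand, summit, count=10):
    return EvidencePeak(
        kind, GenomicInterval(scaffold, summit, summit + 1, strand), summit, count
    )


class TestAssignment:
    def test_containment_and_strand(self):
        tus = [make_tu("t1", "s1", "+", [(1000, 2000)])]
        inside = peak("SL", "s1", "+", 1500)
        wrong_strand = peak("SL", "s1", "-", 1500)
        out = assign_peaks_to_tu(tus, [inside, wrong_strand])
        sl, _ = out.by_tu["t1"]
        assert sl == [inside]

    def test_end_slack_extends_assignment(self):
        tus = [make_tu("t1", "s1", "+", [(1000, 2000)])]
        upstream = peak("SL", "s1", "+", 980)  # 20 nt upstream
        far = peak("SL", "s1", "+", 900)  # 100 nt upstream
        out = assign_peaks_to_tu(tus, [upstream, far], end_slack=50)
        sl, _ = out.by_tu["t1"]
        assert sl == [upstream]

    def test_multi_tu_assignment_reported(self):
        tus = [
            make_tu("t1", "s1", "+", [(1000, 2000)]),
            make_tu("t2", "s1", "+", [(1900, 3000)]),
        ]
        shared = peak("SL", "s1", "+", 1950)
        out = assign_peaks_to_tu(tus, [shared])
        assert out.by_tu["t1"][0] == [shared]
        assert out.by_tu["t2"][0] == [shared]
        assert out.multi_assigned == [(shared, ["t1", "t2"])]


class TestCutTu:
    def test_two_sl_sites_partition(self):
        tu = make_tu("t1", "s1", "+", [(1000, 9000)])
        genes = cut_tu(
            tu,
            [peak("SL", "s1", "+", 1000), peak("SL", "s1", "+", 5000)],
            [peak("POLYA", "s1", "+", 4800), peak("POLYA", "s1", "+", 8999)],
        )
        assert [(g.interval.start, g.interval.end) for g in genes] == [
            (1000, 4801),
            (5000, 9000),
        ]
        assert all(g.has_sl_5p and g.has_polya_3p for g in genes)
        assert [g.polya_summit for g in genes] == [4800, 8999]

    def test_sl_without_polya_runs_to_tu_end(self):
        tu = make_tu("t1", "s1", "+", [(1000, 9000)])
        (gene,) = cut_tu(tu, [peak("SL", "s1", "+", 1000)], [])
        assert (gene.interval.start, gene.interval.end) == (1000, 9000)
        assert gene.has_sl_5p and not gene.has_polya_3p

    def test_minus_strand_mirrors_plus(self):
        # the same layout reflected around position 10000
        M = 10_000
        tu_plus = make_tu("t", "s1", "+", [(1000, 9000)])
        tu_minus = make_tu("t", "s1", "-", [(M - 9000, M - 1000)])
        sl_p = [peak("SL", "s1", "+", 1000), peak("SL", "s1", "+", 5000)]
        pa_p = [peak("POLYA", "s1", "+", 4800), peak("POLYA", "s1", "+", 8999)]
        sl_m = [peak("SL", "s1", "-", M - 1 - 1000), peak("SL", "s1", "-", M - 1 - 5000)]
        pa_m = [
            peak("POLYA", "s1", "-", M - 1 - 4800),
            peak("POLYA", "s1", "-", M - 1 - 8999),
        ]
        plus = cut_tu(tu_plus, sl_p, pa_p)
        minus = cut_tu(tu_minus, sl_m, pa_m)
        reflected = sorted(
            (M - g.interval.end, M - g.interval.start, g.has_sl_5p, g.has_polya_3p)
            for g in minus
        )
        direct = sorted(
            (g.interval.start, g.interval.end, g.has_sl_5p, g.has_polya_3p)
            for g in plus
        )
        assert reflected == direct

    def test_no_sl_returns_single_no_sl_gene(self):
        tu = make_tu("t1", "s1", "+", [(1000, 3000)])
        (gene,) = cut_tu(tu, [], [])
        assert (gene.interval.start, gene.interval.end) == (1000, 3000)
        assert not gene.has_sl_5p and not gene.has_polya_3p

    def test_no_sl_with_polya_trims_three_prime(self):
        tu = make_tu("t1", "s1", "+", [(1000, 3000)])
        (gene,) = cut_tu(tu, [], [peak("POLYA", "s1", "+", 2499)])
        assert (gene.interval.start, gene.interval.end) == (1000, 2500)
        assert gene.has_polya_3p and gene.polya_summit == 2499

    def test_leader_segment_emitted_without_sl(self):
        tu = make_tu("t1", "s1", "+", [(1000, 5000)])
        genes = cut_tu(tu, [peak("SL", "s1", "+", 2000)], [])
        assert [(g.interval.start, g.interval.end, g.has_sl_5p) for g in genes] == [
            (1000, 2000, False),
            (2000, 5000, True),
        ]

    def test_short_leader_dropped(self):
        tu = make_tu("t1", "s1", "+", [(1000, 5000)])
        genes = cut_tu(tu, [peak("SL", "s1", "+", 1050)], [])
        assert len(genes) == 1
        assert genes[0].interval.start == 1050

    def test_strongest_polya_wins_in_segment(self):
        tu = make_tu("t1", "s1", "+", [(1000, 9000)])
        (gene,) = cut_tu(
            tu,
            [peak("SL", "s1", "+", 1000)],
            [peak("POLYA", "s1", "+", 4000, count=20), peak("POLYA", "s1", "+", 6000, count=5)],
        )
        assert gene.polya_summit == 4000

    def test_intronic_sl_summit_snapped_downstream(self):
        tu = make_tu("t1", "s1", "+", [(1000, 2000), (3000, 5000)])
        genes = cut_tu(tu, [peak("SL", "s1", "+", 2500)], [])
        assert genes[-1].interval.start == 3000
        assert "sl_snapped" in genes[-1].notes

    def test_upstream_sl_extends_five_prime_end(self):
        tu = make_tu("t1", "s1", "+", [(1000, 3000)])
        (gene,) = cut_tu(tu, [peak("SL", "s1", "+", 970)], [])
        assert gene.interval.start == 970
        assert "5p_extended" in gene.notes

    def test_min_gene_len_drops_fragments(self):
        tu = make_tu("t1", "s1", "+", [(1000, 3000)])
        genes = cut_tu(
            tu,
            [peak("SL", "s1", "+", 1000), peak("SL", "s1", "+", 2950)],
            [],
            CutParams(min_gene_len=100),
        )
        # second segment is 50 nt -> dropped
        assert [g.interval.start for g in genes] == [1000]

    def test_strand_inconsistent_peak_is_internal_error(self):
        tu = make_tu("t1", "s1", "+", [(1000, 3000)])
        with pytest.raises(ValidationError, match="assignment bug"):
            cut_tu(tu, [peak("SL", "s1", "-", 1500)], [])

    def test_partition_and_evidence_properties(self, clean_sim):
        sl_track = pileup_end_positions(clean_sim.sl_placements, "SL")
        pa_track = pileup_end_positions(clean_sim.polya_placements, "POLYA")
        peaks = call_peaks(sl_track) + call_peaks(pa_track)
        genes, _, assignment = cut_all(clean_sim.tus, peaks)
        by_parent = {}
        for g in genes:
            by_parent.setdefault(g.parent_tu_id, []).append(g)
        tus = {t.tu_id: t for t in clean_sim.tus}
        for parent, children in by_parent.items():
            span = tus[parent].interval
            children = sorted(children, key=lambda g: g.interval.start)
            for a, b in zip(children, children[1:]):
                assert a.interval.end <= b.interval.start  # pairwise disjoint
            for g in children:
                assert g.interval.start >= span.start - 50
                assert g.interval.end <= span.end + 50
            # every assigned SL summit surfaces as exactly one child 5' boundary
            sl_peaks, _ = assignment.by_tu[parent]
            child_summits = [g.sl_summit for g in children if g.has_sl_5p]
            expected = sorted({p.summit for p in sl_peaks if span.contains(p.summit)})
            assert sorted(child_summits) == expected


class TestClassification:
    def test_single_and_multiple_parents(self):
        tu1 = make_tu("t1", "s1", "+", [(1000, 3000)])
        genes1 = cut_tu(tu1, [peak("SL", "s1", "+", 1000)], [])
        tu2 = make_tu("t2", "s1", "+", [(5000, 12000)])
        genes2 = cut_tu(
            tu2,
            [peak("SL", "s1", "+", p) for p in (5000, 7000, 9000)],
            [],
        )
        annotated, summary = classify_genes(genes1 + genes2)
        assert {g.classification for g in annotated if g.parent_tu_id == "t1"} == {
            "SL_SINGLE"
        }
        assert {g.classification for g in annotated if g.parent_tu_id == "t2"} == {
            "SL_MULTIPLE_PARENT"
        }
        assert summary["n_single_sl"] == 1
        assert summary["n_multiple_sl"] == 1

    def test_percentages_on_known_mix(self):
        genes = []
        for i in range(4):  # 4 single-SL parents
            tu = make_tu(f"s{i}", "s1", "+", [(1000 + 10_000 * i, 3000 + 10_000 * i)])
            genes += cut_tu(tu, [peak("SL", "s1", "+", tu.interval.start)], [])
        for i in range(2):  # 2 multi-SL parents
            base = 100_000 + 10_000 * i
            tu = make_tu(f"m{i}", "s1", "+", [(base, base + 5000)])
            genes += cut_tu(
                tu,
                [peak("SL", "s1", "+", base), peak("SL", "s1", "+", base + 2000)],
                [],
            )
        for i in range(4):  # 4 no-SL parents
            tu = make_tu(f"n{i}", "s1", "+", [(200_000 + 10_000 * i, 202_000 + 10_000 * i)])
            genes += cut_tu(tu, [], [])
        _, summary = classify_genes(genes)
        assert summary["pct_single_sl"] == pytest.approx(40.0)
        assert summary["pct_multiple_sl"] == pytest.approx(20.0)
        assert summary["pct_no_sl"] == pytest.approx(40.0)


def test_clean_fixture_boundary_recovery(clean_sim):
    """Every planted gene boundary is recovered exactly on jitterless data."""
    sl = call_peaks(pileup_end_positions(clean_sim.sl_placements, "SL"))
    pa = call_peaks(pileup_end_positions(clean_sim.polya_placements, "POLYA"))
    genes, _, _ = cut_all(clean_sim.tus, sl + pa)
    called = {
        (g.scaffold_id, g.strand, g.interval.start, g.interval.end)
        for g in genes
        if g.has_sl_5p
    }
    expected = {
        (g.scaffold, g.strand, g.start, g.end)
        for g in clean_sim.truth.genes
        if g.has_evidence
    }
    assert expected <= called
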