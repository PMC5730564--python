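"""Shared fixtures: small synthetic datasets and gene-model builders."""

from __future__ import annotations

import pytest

from tbone.models import GeneModel, GenomicInterval, TranscriptionalUnit
from tbone.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def clean_sim():
    """A zero-jitter, zero-error 50-TU dataset with known boundaries."""
    return simulate(SimulationConfig(seed=101, n_tus=50))


@pytest.fixture(scope="session")
def clean_genome(clean_sim):
    return clean_sim.genome_dict


def make_tu(
    tu_id: str,
    scaffold: str,
    strand: str,
    exons: list[tuple[int, int]],
    rpkm: float = 1.0,
) -> TranscriptionalUnit:
    return TranscriptionalUnit.from_exons(
        tu_id,
        [GenomicInterval(scaffold, s, e, strand) for s, e in exons],
        strand,
        expression_rpkm=rpkm,
    )


def make_gene(
    gene_id: str,
    scaffold: str,
    strand: str,
    exons: list[tuple[int, int]],
    has_sl: bool = False,
    has_polya: bool = False,
    orf=None,
) -> GeneModel:
    ivs = [GenomicInterval(scaffold, s, e, strand) for s, e in exons]
    return GeneModel(
        gene_id=gene_id,
        parent_tu_id=gene_id,
        interval=GenomicInterval(scaffold, ivs[0].start, ivs[-1].end, strand),
        exons=ivs,
        has_sl_5p=has_sl,
        has_polya_3p=has_polya,
        sl_summit=(ivs[0].start if strand == "+" else ivs[-1].end - 1) if has_sl else None,
        polya_summit=(ivs[-1].end - 1 if strand == "+" else ivs[0].start)
        if has_polya
        else None,
        orf=orf,
    )
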