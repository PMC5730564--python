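"""Synthetic genomes with known transcript boundaries, evidence reads,
antisense contamination, repeats and planted duplications.

The generator emulates the data a boundary-annotation run consumes: a
multi-scaffold genome; strand-assigned, multi-exon, possibly polycistronic
transcriptional units; SL-leader-prefixed 5' reads and T-fill 3' reads with
Poisson site counts and optional positional jitter; antisense transcripts at
a controlled read-count ratio; repeat intervals; and planted genomic
duplications.  Every output is deterministic under the master seed, with one
pseudo-random stream per output so adding one file never perturbs another.

Machine-readable ground truth (gene boundaries, site counts, antisense pairs,
duplication registry) is emitted alongside, so each pipeline stage can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .models import (
    GenomeSequence,
    GenomicInterval,
    RepeatMask,
    TranscriptionalUnit,
    revcomp,
)

BASES = "ACGT"

# Default spliced-leader used by the generator: a fixed 20-mer kept in the
# configuration (real leaders are organism-specific; the detector takes the
# leader as required input).
DEFAULT_SL_LEADER = "GGTTTAACTACGGGAGTTTG"

_STREAMS = {
    "genome": 1,
    "layout": 2,
    "sl_reads": 3,
    "polya_reads": 4,
    "antisense": 5,
    "expression": 6,
    "repeats": 7,
    "dups": 8,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_scaffolds: int = 4
    scaffold_len: int = 150_000
    n_tus: int = 50
    genes_per_tu: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    no_evidence_fraction: float = 0.2
    sl_leader: str = DEFAULT_SL_LEADER
    reads_per_sl_site: float = 20.0
    reads_per_polya_site: float = 20.0
    position_jitter_sd: float = 0.0
    antisense_fraction: float = 0.2
    antisense_count_ratio: float = 5.0  # inf plants a zero-count antisense
    repeat_fraction: float = 0.05
    planted_dups: tuple = ()  # (length, identity, orientation) triples
    error_rate: float = 0.0
    read_length: int = 60

    def __post_init__(self) -> None:
        for name in (
            "no_evidence_fraction",
            "antisense_fraction",
            "repeat_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if abs(sum(self.genes_per_tu.values()) - 1.0) > 1e-9:
            raise ConfigError("genes_per_tu probabilities must sum to 1")
        if self.position_jitter_sd < 0:
            raise ConfigError("position_jitter_sd must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class GeneTruth:
    tu_id: str
    gene_index: int  # 1-based, transcript orientation
    scaffold: str
    strand: str
    start: int
    end: int
    sl_pos: int
    polya_pos: int
    sl_reads: int = 0
    polya_reads: int = 0
    has_evidence: bool = True


@dataclass
class DupTruth:
    scaffold_a: str
    start_a: int
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    orientation: str
    identity: float
    length: int


@dataclass
class GroundTruth:
    genes: list[GeneTruth] = field(default_factory=list)
    antisense_pairs: list[dict] = field(default_factory=list)
    dups: list[DupTruth] = field(default_factory=list)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: list[GenomeSequence]
    tus: list[TranscriptionalUnit]
    sl_reads: list[tuple[str, str]]
    tfill_reads: list[tuple[str, str]]
    sl_placements: list[tuple[str, str, int]]
    polya_placements: list[tuple[str, str, int]]
    repeats: RepeatMask
    expression: dict[str, float]
    read_counts: dict[str, int]
    truth: GroundTruth

    @property
    def genome_dict(self) -> dict[str, str]:
        return {g.scaffold_id: g.sequence for g in self.genome}

    def write_outputs(self, outdir: str, provenance: Optional[str] = None) -> None:
        import os

        from . import io_formats

        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(outdir, name)  # noqa: E731
        io_formats.write_fasta(self.genome, j("genome.fasta"), provenance=provenance)
        io_formats.write_tu_gtf(self.tus, j("tus.gtf"), provenance=provenance)
        _write_fastq(self.sl_reads, j("sl_reads.fastq"))
        _write_fastq(self.tfill_reads, j("tfill_reads.fastq"))
        _write_placements(self.sl_placements, j("sl_placements.bed"))
        _write_placements(self.polya_placements, j("polya_placements.bed"))
        io_formats.write_bed(self.repeats.intervals, j("repeats.bed"))
        io_formats.write_expression_tsv(self.expression, j("expression.tsv"))
        io_formats.write_expression_tsv(
            {k: float(v) for k, v in self.read_counts.items()}, j("read_counts.tsv")
        )
        _write_truth(self.truth, outdir)


def _write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _write_placements(placements: list[tuple[str, str, int]], path: str) -> None:
    with open(path, "w") as fh:
        for i, (scaf, strand, pos) in enumerate(placements):
            fh.write(f"{scaf}\t{pos}\t{pos + 1}\tp{i}\t0\t{strand}\n")


def _write_truth(truth: GroundTruth, outdir: str) -> None:
    import os

    with open(os.path.join(outdir, "truth_genes.tsv"), "w") as fh:
        fh.write(
            "tu_id\tgene_index\tscaffold\tstrand\tstart\tend\tsl_pos\tpolya_pos\t"
            "sl_reads\tpolya_reads\thas_evidence\n"
        )
        for g in truth.genes:
            fh.write(
                f"{g.tu_id}\t{g.gene_index}\t{g.scaffold}\t{g.strand}\t{g.start}\t"
                f"{g.end}\t{g.sl_pos}\t{g.polya_pos}\t{g.sl_reads}\t{g.polya_reads}\t"
                f"{int(g.has_evidence)}\n"
            )
    with open(os.path.join(outdir, "truth_antisense.tsv"), "w") as fh:
        fh.write("sense_id\tantisense_id\tcount_sense\tcount_antisense\n")
        for row in truth.antisense_pairs:
            fh.write(
                f"{row['sense_id']}\t{row['antisense_id']}\t{row['count_sense']}\t"
                f"{row['count_antisense']}\n"
            )
    with open(os.path.join(outdir, "truth_dups.tsv"), "w") as fh:
        fh.write(
            "scaffold_a\tstart_a\tend_a\tscaffold_b\tstart_b\tend_b\torientation\t"
            "identity\tlength\n"
        )
        for d in truth.dups:
            fh.write(
                f"{d.scaffold_a}\t{d.start_a}\t{d.end_a}\t{d.scaffold_b}\t{d.start_b}"
                f"\t{d.end_b}\t{d.orientation}\t{d.identity:.6g}\t{d.length}\n"
            )


# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


@dataclass
class _GeneDraft:
    start: int
    end: int
    exons: list[tuple[int, int]]


def _draft_gene(rng: np.random.Generator, start: int) -> _GeneDraft:
    """One gene laid out left-to-right in genomic coordinates."""
    n_exons = int(rng.integers(1, 4))
    exon_lens = [int(rng.integers(150, 450)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(80, 250)) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]
    return _GeneDraft(start=start, end=exons[-1][1], exons=exons)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a complete synthetic dataset under ``config``."""
    L = config.scaffold_len
    tu_region_end = int(L * 0.55)
    repeat_region = (int(L * 0.55), int(L * 0.80))
    dup_region = (int(L * 0.80), L)

    rng_genome = config.rng("genome")
    scaffold_ids = [f"scf{i + 1}" for i in range(config.n_scaffolds)]
    seqs = {sid: list(_random_seq(rng_genome, L)) for sid in scaffold_ids}

    # --- TU layout -------------------------------------------------------
    rng_layout = config.rng("layout")
    gene_counts = sorted(config.genes_per_tu)
    gene_probs = [config.genes_per_tu[k] for k in gene_counts]
    cursors = {sid: 500 for sid in scaffold_ids}
    tus: list[TranscriptionalUnit] = []
    truth = GroundTruth()
    evidence_flags: dict[str, bool] = {}

    for t in range(config.n_tus):
        sid = scaffold_ids[t % config.n_scaffolds]
        tu_id = f"TU{t + 1:05d}"
        strand = "+" if rng_layout.random() < 0.5 else "-"
        has_evidence = rng_layout.random() >= config.no_evidence_fraction
        n_genes = (
            1
            if not has_evidence
            else int(rng_layout.choice(gene_counts, p=gene_probs))
        )
        start = cursors[sid]
        drafts: list[_GeneDraft] = []
        pos = start
        for gi in range(n_genes):
            draft = _draft_gene(rng_layout, pos)
            drafts.append(draft)
            pos = draft.end + int(rng_layout.integers(150, 300))
        tu_end = drafts[-1].end
        if tu_end > tu_region_end:
            raise ConfigError(
                f"infeasible packing: {config.n_tus} TUs do not fit in the "
                f"TU region of {config.n_scaffolds} x {L} nt scaffolds"
            )
        cursors[sid] = tu_end + int(rng_layout.integers(400, 800))

        # TU exons: gene exons plus exonic inter-gene spacers
        exons: list[tuple[int, int]] = []
        for i, d in enumerate(drafts):
            exons.extend(d.exons)
            if i + 1 < len(drafts):
                exons.append((d.end, drafts[i + 1].start))
        merged: list[tuple[int, int]] = []
        for s, e in sorted(exons):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        tus.append(
            TranscriptionalUnit.from_exons(
                tu_id,
                [GenomicInterval(sid, s, e, strand) for s, e in merged],
                strand,
                source_tag="sim",
            )
        )
        evidence_flags[tu_id] = has_evidence

        ordered = drafts if strand == "+" else drafts[::-1]
        for gi, d in enumerate(ordered, start=1):
            if strand == "+":
                sl_pos, polya_pos = d.start, d.end - 1
            else:
                sl_pos, polya_pos = d.end - 1, d.start
            truth.genes.append(
                GeneTruth(
                    tu_id=tu_id,
                    gene_index=gi,
                    scaffold=sid,
                    strand=strand,
                    start=d.start,
                    end=d.end,
                    sl_pos=sl_pos,
                    polya_pos=polya_pos,
                    has_evidence=has_evidence,
                )
            )

    # --- antisense contamination ----------------------------------------
    rng_anti = config.rng("antisense")
    sense_candidates = [tu for tu in tus if evidence_flags[tu.tu_id]]
    n_anti = int(round(config.antisense_fraction * len(sense_candidates)))
    read_counts: dict[str, int] = {}
    anti_tus: list[TranscriptionalUnit] = []
    chosen = (
        list(rng_anti.choice(len(sense_candidates), size=n_anti, replace=False))
        if n_anti
        else []
    )
    for idx in sorted(int(i) for i in chosen):
        sense = sense_candidates[idx]
        span = sense.interval
        margin = max(1, span.length // 5)
        a_start = span.start + margin
        a_end = span.end - margin
        if a_end - a_start < 200:
            continue
        anti_strand = "-" if sense.strand == "+" else "+"
        anti_id = f"{sense.tu_id}as"
        anti_tus.append(
            TranscriptionalUnit.from_exons(
                anti_id,
                [GenomicInterval(span.scaffold_id, a_start, a_end, anti_strand)],
                anti_strand,
                source_tag="sim_antisense",
            )
        )
        count_anti = 100
        if np.isinf(config.antisense_count_ratio):
            count_anti = 0
            count_sense = 100
        else:
            count_sense = int(round(count_anti * config.antisense_count_ratio))
        read_counts[sense.tu_id] = count_sense
        read_counts[anti_id] = count_anti
        truth.antisense_pairs.append(
            {
                "sense_id": sense.tu_id,
                "antisense_id": anti_id,
                "count_sense": count_sense,
                "count_antisense": count_anti,
            }
        )
    for tu in tus:
        if tu.tu_id not in read_counts:
            read_counts[tu.tu_id] = int(rng_anti.integers(50, 500))
    tus = tus + anti_tus

    # --- expression -------------------------------------------------------
    rng_expr = config.rng("expression")
    expression: dict[str, float] = {}
    for tu in tus:
        rpkm = float(rng_expr.lognormal(mean=1.0, sigma=1.2))
        tu.expression_rpkm = rpkm
        expression[tu.tu_id] = rpkm

    # --- repeats ----------------------------------------------------------
    rng_rep = config.rng("repeats")
    target = int(config.repeat_fraction * L)
    region_len = repeat_region[1] - repeat_region[0]
    if target > region_len:
        raise ConfigError("repeat_fraction too high for the repeat region")
    repeat_ivs: list[GenomicInterval] = []
    for sid in scaffold_ids:
        covered = 0
        pos = repeat_region[0]
        while covered < target and pos < repeat_region[1] - 200:
            length = int(rng_rep.integers(200, 800))
            length = min(length, repeat_region[1] - pos, target - covered + 200)
            if length < 50:
                break
            repeat_ivs.append(GenomicInterval(sid, pos, pos + length, "."))
            covered += length
            pos += length + int(rng_rep.integers(100, 400))
    repeats = RepeatMask(repeat_ivs)

    # --- planted duplications --------------------------------------------
    rng_dup = config.rng("dups")
    dup_cursors = {sid: dup_region[0] + 100 for sid in scaffold_ids}
    for i, (length, identity, orientation) in enumerate(config.planted_dups):
        length = int(length)
        sid_a = scaffold_ids[i % config.n_scaffolds]
        sid_b = scaffold_ids[(i + 1) % config.n_scaffolds]
        a0 = dup_cursors[sid_a]
        dup_cursors[sid_a] = a0 + length + 200
        b0 = dup_cursors[sid_b]
        dup_cursors[sid_b] = b0 + length + 200
        if dup_cursors[sid_a] > L or dup_cursors[sid_b] > L:
            raise ConfigError("infeasible packing: planted duplications overflow")
        src = "".join(seqs[sid_a][a0 : a0 + length])
        n_sub = int(round(length * (1.0 - identity)))
        copy = list(src if orientation == "same" else revcomp(src))
        if n_sub:
            positions = rng_dup.choice(length, size=n_sub, replace=False)
            for p in sorted(int(x) for x in positions):
                alts = [b for b in BASES if b != copy[p]]
                copy[p] = alts[int(rng_dup.integers(0, 3))]
        seqs[sid_b][b0 : b0 + length] = copy
        _force_flank_mismatch(seqs, sid_a, a0, a0 + length, sid_b, b0, b0 + length, orientation)
        realized = 1.0 - n_sub / length
        iv_a = (sid_a, a0, a0 + length)
        iv_b = (sid_b, b0, b0 + length)
        if iv_b < iv_a:
            iv_a, iv_b = iv_b, iv_a
        truth.dups.append(
            DupTruth(
                scaffold_a=iv_a[0],
                start_a=iv_a[1],
                end_a=iv_a[2],
                scaffold_b=iv_b[0],
                start_b=iv_b[1],
                end_b=iv_b[2],
                orientation=orientation,
                identity=realized,
                length=length,
            )
        )

    genome = [GenomeSequence(sid, "".join(seqs[sid])) for sid in scaffold_ids]
    genome_dict = {g.scaffold_id: g.sequence for g in genome}

    # --- evidence reads ---------------------------------------------------
    rng_sl = config.rng("sl_reads")
    rng_pa = config.rng("polya_reads")
    sl_reads: list[tuple[str, str]] = []
    tfill_reads: list[tuple[str, str]] = []
    sl_placements: list[tuple[str, str, int]] = []
    polya_placements: list[tuple[str, str, int]] = []
    leader = config.sl_leader.upper()

    def jitter(rng: np.random.Generator) -> int:
        if config.position_jitter_sd == 0:
            return 0
        return int(round(rng.normal(0.0, config.position_jitter_sd)))

    def with_errors(rng: np.random.Generator, seq: str) -> str:
        if config.error_rate == 0:
            return seq
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < config.error_rate:
                alts = [b for b in BASES if b != chars[i]]
                chars[i] = alts[int(rng.integers(0, 3))]
        return "".join(chars)

    for g in truth.genes:
        if not g.has_evidence:
            continue
        chrom = genome_dict[g.scaffold]
        n_sl = int(rng_sl.poisson(config.reads_per_sl_site))
        g.sl_reads = n_sl
        for r in range(n_sl):
            pos = min(max(g.sl_pos + jitter(rng_sl), 0), len(chrom) - 1)
            suffix_len = int(rng_sl.integers(min(10, len(leader)), len(leader) + 1))
            body = config.read_length - suffix_len
            if g.strand == "+":
                genomic = chrom[pos : pos + body]
            else:
                genomic = revcomp(chrom[max(0, pos - body + 1) : pos + 1])
            seq = leader[-suffix_len:] + with_errors(rng_sl, genomic)
            sl_reads.append((f"{g.tu_id}.g{g.gene_index}.sl{r}", seq))
            sl_placements.append((g.scaffold, g.strand, pos))
        n_pa = int(rng_pa.poisson(config.reads_per_polya_site))
        g.polya_reads = n_pa
        for r in range(n_pa):
            pos = min(max(g.polya_pos + jitter(rng_pa), 0), len(chrom) - 1)
            body = config.read_length
            if g.strand == "+":
                genomic = chrom[max(0, pos - body + 1) : pos + 1]
            else:
                genomic = revcomp(chrom[pos : pos + body])
            tail = "A" * int(rng_pa.integers(6, 13))
            seq = with_errors(rng_pa, genomic) + tail
            tfill_reads.append((f"{g.tu_id}.g{g.gene_index}.pa{r}", seq))
            polya_placements.append((g.scaffold, g.strand, pos))

    tus.sort(key=lambda t: (t.interval.sort_key(), t.tu_id))
    return SimulationResult(
        config=config,
        genome=genome,
        tus=tus,
        sl_reads=sl_reads,
        tfill_reads=tfill_reads,
        sl_placements=sl_placements,
        polya_placements=polya_placements,
        repeats=repeats,
        expression=expression,
        read_counts=read_counts,
        truth=truth,
    )


def _force_flank_mismatch(
    seqs: dict[str, list[str]],
    sid_a: str,
    a0: int,
    a1: int,
    sid_b: str,
    b0: int,
    b1: int,
    orientation: str,
) -> None:
    """Make the bases flanking a planted copy disagree with the source's
    continuation, so the planted block has sharp, well-defined boundaries."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def force_diff(sid: str, pos: int, other: str) -> None:
        if 0 <= pos < len(seqs[sid]):
            if seqs[sid][pos] == other:
                seqs[sid][pos] = "A" if other != "A" else "C"

    if orientation == "same":
        if a0 - 1 >= 0:
            force_diff(sid_b, b0 - 1, seqs[sid_a][a0 - 1])
        if a1 < len(seqs[sid_a]):
            force_diff(sid_b, b1, seqs[sid_a][a1])
    else:
        # copy left flank pairs with the complement of the source's right flank
        if a1 < len(seqs[sid_a]):
            force_diff(sid_b, b0 - 1, comp[seqs[sid_a][a1]])
        if a0 - 1 >= 0:
            force_diff(sid_b, b1, comp[seqs[sid_a][a0 - 1]])


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a config from a flat key-value mapping (pipeline config files)."""
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigError(f"unknown simulation key {key!r}")
        ftype = fields[key].type
        if key == "genes_per_tu":
            parsed = {}
            for part in str(value).split(","):
                k, v = part.split(":")
                parsed[int(k)] = float(v)
            kwargs[key] = parsed
        elif key == "planted_dups":
            dups = []
            if str(value).strip():
                for part in str(value).split(";"):
                    length, ident, orient = part.split(",")
                    dups.append((int(length), float(ident), orient.strip()))
            kwargs[key] = tuple(dups)
        elif key == "sl_leader":
            kwargs[key] = str(value)
        elif ftype in ("int", int):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    if "seed" not in kwargs:
        raise ConfigError("simulation config requires a seed")
    kwargs["seed"] = int(kwargs["seed"])
    for intkey in ("n_scaffolds", "scaffold_len", "n_tus", "read_length"):
        if intkey in kwargs:
            kwargs[intkey] = int(kwargs[intkey])
    return SimulationConfig(**kwargs)
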