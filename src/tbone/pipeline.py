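"""End-to-end pipeline orchestration with a flat key-value configuration.

Stages run in a configured order; every artifact carries a provenance header
``#tbone <version> <config-sha>`` and the log records per-stage record counts
in and out.  Identical configs and seeds reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
import os
from typing import Optional

from . import io_formats
from .codon import build_weight_matrix, write_matrix_tsv
from .cutting import CutParams, cut_all
from .dup import duplicated_fraction, find_dup_blocks, mask_genome
from .errors import ConfigError
from .evidence import call_peaks, pileup_end_positions
from .filters import filter_antisense, filter_low_expression_novel
from .orfs import call_orfs, merge_split_transcripts, transcript_sequence
from .redundancy import assign_cluster_names, cluster_nt
from .simulate import SimulationConfig, config_from_mapping, simulate
from .stats import summarize

log = logging.getLogger("tbone")

DEFAULT_STAGES = (
    "simulate",
    "evidence",
    "peaks",
    "filter",
    "cut",
    "orf",
    "merge",
    "cluster",
    "stats",
)

KNOWN_STAGES = set(DEFAULT_STAGES) | {"codon", "dup"}


def read_config(path: str) -> dict[str, str]:
    """Flat ``key = value`` configuration (``#`` comments allowed)."""
    config: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key = value")
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    return config


def config_provenance(config: dict) -> str:
    from . import __version__

    blob = "\n".join(f"{k}={config[k]}" for k in sorted(config)).encode()
    return f"tbone {__version__} {hashlib.sha1(blob).hexdigest()[:12]}"


def run_pipeline(config: dict | str, outdir: str) -> dict:
    """Run the configured stages; returns a dict of in-memory results.

    The configuration mixes simulation keys (prefixed ``sim_``), threshold
    keys, and a ``stages`` list.  Missing inputs for a stage fail fast with
    the stage name.
    """
    if isinstance(config, str):
        config = read_config(config)
    os.makedirs(outdir, exist_ok=True)
    provenance = config_provenance(config)
    stages = [
        s.strip()
        for s in config.get("stages", ",".join(DEFAULT_STAGES)).split(",")
        if s.strip()
    ]
    for stage in stages:
        if stage not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage name {stage!r}")

    def cfloat(key: str, default: float) -> float:
        return float(config.get(key, default))

    def cint(key: str, default: int) -> int:
        return int(config.get(key, default))

    state: dict = {"provenance": provenance}
    j = lambda name: os.path.join(outdir, name)  # noqa: E731

    for stage in stages:
        if stage == "simulate":
            sim_keys = {
                k[len("sim_") :]: v for k, v in config.items() if k.startswith("sim_")
            }
            if "seed" in config and "seed" not in sim_keys:
                sim_keys["seed"] = config["seed"]
            sim_config: SimulationConfig = config_from_mapping(sim_keys)
            sim = simulate(sim_config)
            sim.write_outputs(j("sim"), provenance=provenance)
            state["sim"] = sim
            state["genome"] = sim.genome_dict
            state["tus"] = sim.tus
            state["repeats"] = sim.repeats
            state["read_counts"] = sim.read_counts
            log.info("simulate: %d TUs, %d scaffolds", len(sim.tus), len(sim.genome))
        elif stage == "evidence":
            sim = _require(state, "sim", stage)
            state["sl_track"] = pileup_end_positions(
                sim.sl_placements, "SL", genome=state["genome"]
            )
            state["polya_track"] = pileup_end_positions(
                sim.polya_placements, "POLYA", genome=state["genome"]
            )
            io_formats.write_bedgraph(state["sl_track"], j("sl"), provenance=provenance)
            io_formats.write_bedgraph(
                state["polya_track"], j("polya"), provenance=provenance
            )
            log.info(
                "evidence: %d SL / %d polyA placements",
                state["sl_track"].total(),
                state["polya_track"].total(),
            )
        elif stage == "peaks":
            min_count = cint("min_site_count", 5)
            merge_dist = cint("merge_distance", 10)
            sl = call_peaks(_require(state, "sl_track", stage), min_count, merge_dist)
            pa = call_peaks(
                _require(state, "polya_track", stage), min_count, merge_dist
            )
            state["peaks"] = sl + pa
            io_formats.write_peaks_bed(state["peaks"], j("peaks.bed"), provenance)
            log.info("peaks: %d SL, %d polyA", len(sl), len(pa))
        elif stage == "filter":
            tus = _require(state, "tus", stage)
            kept, discarded, report = filter_antisense(
                tus,
                _require(state, "read_counts", stage),
                ratio_threshold=cfloat("antisense_ratio", 5.0),
                min_overlap_frac=cfloat("min_overlap_frac", 0.5),
            )
            reference = set(config.get("reference_overlaps", "").split(",")) - {""}
            kept2, low = filter_low_expression_novel(
                kept, reference, rpkm_min=cfloat("rpkm_min", 0.5)
            )
            state["tus"] = kept2
            with open(j("filter_report.tsv"), "w") as fh:
                fh.write(f"#{provenance}\n")
                fh.write("tu_id\treason\tdetail\n")
                for row in report:
                    fh.write(
                        f"{row['discarded']}\tantisense\tratio={row['ratio']:.3g}\n"
                    )
                for tu in low:
                    fh.write(f"{tu.tu_id}\tlow_expression\trpkm={tu.expression_rpkm:.3g}\n")
            io_formats.write_tu_gtf(kept2, j("tus_filtered.gtf"), provenance)
            log.info(
                "filter: %d in = %d kept + %d discarded",
                len(tus),
                len(kept2),
                len(discarded) + len(low),
            )
        elif stage == "cut":
            tus = _require(state, "tus", stage)
            peaks = _require(state, "peaks", stage)
            params = CutParams(
                end_slack=cint("end_slack", 50),
                min_gene_len=cint("min_gene_len", 100),
            )
            genes, summary, _ = cut_all(tus, peaks, params)
            state["genes"] = genes
            state["cut_summary"] = summary
            io_formats.write_gtf(genes, j("genes.gtf"), provenance)
            log.info("cut: %d TUs -> %d genes", len(tus), len(genes))
        elif stage == "orf":
            genes = _require(state, "genes", stage)
            call_orfs(genes, _require(state, "genome", stage), cint("min_aa", 100))
            n = sum(1 for g in genes if g.orf is not None)
            log.info("orf: %d/%d genes with ORF", n, len(genes))
        elif stage == "merge":
            genes = _require(state, "genes", stage)
            merged, events = merge_split_transcripts(
                genes,
                _require(state, "repeats", stage),
                max_gap=cint("max_gap", 10_000),
                min_repeat_frac=cfloat("min_repeat_frac", 0.5),
                genome=state.get("genome"),
            )
            state["genes"] = merged
            with open(j("merge_report.tsv"), "w") as fh:
                fh.write(f"#{provenance}\n")
                fh.write("upstream\tdownstream\tgap_nt\trepeat_frac\n")
                for ev in events:
                    fh.write(
                        f"{ev.upstream_id}\t{ev.downstream_id}\t{ev.gap_nt}\t"
                        f"{ev.repeat_frac:.3f}\n"
                    )
            io_formats.write_gtf(merged, j("genes_merged.gtf"), provenance)
            log.info("merge: %d in = %d kept after %d merges", len(genes), len(merged), len(events))
        elif stage == "cluster":
            genes = _require(state, "genes", stage)
            genome = _require(state, "genome", stage)
            seqs = {g.gene_id: transcript_sequence(g, genome) for g in genes}
            assignment = cluster_nt(
                seqs, identity_threshold=cfloat("identity_threshold", 0.95)
            )
            names = assign_cluster_names(assignment, prefix=config.get("prefix", "G"))
            state["clusters"] = assignment
            with open(j("clusters.tsv"), "w") as fh:
                fh.write(f"#{provenance}\n")
                fh.write("member\trepresentative\tidentity\tname\n")
                for member in sorted(assignment.assignment):
                    rep, ident = assignment.assignment[member]
                    fh.write(f"{member}\t{rep}\t{ident:.4f}\t{names[member]}\n")
            log.info(
                "cluster: %d transcripts -> %d clusters",
                len(seqs),
                assignment.n_clusters(),
            )
        elif stage == "codon":
            genes = _require(state, "genes", stage)
            genome = _require(state, "genome", stage)
            cds = {}
            for g in genes:
                if g.orf is None:
                    continue
                seq = transcript_sequence(g, genome)
                cds[g.gene_id] = seq[g.orf.start : g.orf.end]
            if cds:
                expr = {g.gene_id: 0.0 for g in genes}
                for tu in state.get("tus", []):
                    for g in genes:
                        if g.parent_tu_id == tu.tu_id:
                            expr[g.gene_id] = tu.expression_rpkm
                matrix = build_weight_matrix(cds, expr, top_n=cint("top_n", 100))
                write_matrix_tsv(matrix, j("codon_matrix.tsv"), provenance)
                state["codon_matrix"] = matrix
                log.info("codon: matrix from %d genes", len(matrix.source_gene_ids))
        elif stage == "dup":
            genome = _require(state, "genome", stage)
            masked = mask_genome(genome, _require(state, "repeats", stage))
            blocks = find_dup_blocks(
                masked,
                k=cint("dup_k", 16),
                min_len=cint("dup_min_len", 500),
                min_identity=cfloat("dup_min_identity", 0.95),
            )
            state["dup_blocks"] = blocks
            nt, frac = duplicated_fraction(blocks, genome)
            with open(j("dup_blocks.tsv"), "w") as fh:
                fh.write(f"#{provenance}\n")
                fh.write(
                    "scaffold_a\tstart_a\tend_a\tscaffold_b\tstart_b\tend_b\t"
                    "orientation\tidentity\taligned_length\n"
                )
                for blk in blocks:
                    a, b = blk.interval_a, blk.interval_b
                    fh.write(
                        f"{a.scaffold_id}\t{a.start}\t{a.end}\t{b.scaffold_id}\t"
                        f"{b.start}\t{b.end}\t{blk.orientation}\t{blk.identity:.4f}\t"
                        f"{blk.aligned_length}\n"
                    )
            log.info("dup: %d blocks, %d nt (%.2f%%)", len(blocks), nt, 100 * frac)
        elif stage == "stats":
            summary = summarize(
                _require(state, "genes", stage),
                state.get("tus", []),
                state.get("clusters"),
            )
            summary.to_tsv(j("summary.tsv"), provenance)
            state["summary"] = summary
            log.info("stats: %d genes summarized", summary.n_genes)
    return state


def _require(state: dict, key: str, stage: str):
    if key not in state or state[key] is None:
        raise ConfigError(f"stage {stage!r}: missing input {key!r}")
    return state[key]
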