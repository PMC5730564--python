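"""Readers and writers for the on-disk formats the toolkit exchanges.

This module is the only place where coordinate conventions are converted:
internally everything is 0-based half-open; GTF is 1-based inclusive;
BED and bedGraph are 0-based half-open.

All writers are deterministic: records are sorted by
(scaffold, start, end, id) and two runs over the same data produce
byte-identical files.  An optional ``provenance`` string is written as a
leading ``#`` comment line; all readers skip comment lines.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

from .errors import FormatError, ValidationError
from .models import (
    EndSignalTrack,
    EvidencePeak,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    NUCLEOTIDES,
    RepeatMask,
    TranscriptionalUnit,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a FASTA file into upper-cased :class:`GenomeSequence` records.

    Raises :class:`FormatError` naming the line number for malformed headers,
    characters outside A/C/G/T/N, or duplicate record IDs.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    name: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {name!r} has no sequence")
        records.append(GenomeSequence(name, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if name in seen:
                    raise FormatError(f"line {lineno}: duplicate ID {name!r}")
                seen.add(name)
                chunks = []
                header_line = lineno
            else:
                if name is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                up = line.upper()
                bad = set(up) - NUCLEOTIDES
                if bad:
                    raise FormatError(
                        f"line {lineno}: illegal character(s) {sorted(bad)}"
                    )
                chunks.append(up)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(
    records: Iterable[GenomeSequence] | dict[str, str],
    path: str,
    width: int = 70,
    provenance: Optional[str] = None,
) -> None:
    if isinstance(records, dict):
        records = [GenomeSequence(k, v) for k, v in records.items()]
    records = sorted(records, key=lambda r: r.scaffold_id)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for rec in records:
            fh.write(f">{rec.scaffold_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

def _parse_gtf_attrs(field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def _fmt_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def _read_gtf_rows(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            try:
                start = int(cols[3])
                end = int(cols[4])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise FormatError(f"line {lineno}: invalid GTF coordinates {start}-{end}")
            attrs = _parse_gtf_attrs(cols[8], lineno)
            # 1-based inclusive -> 0-based half-open
            yield lineno, cols[0], cols[2], start - 1, end, cols[6], attrs


def read_gtf(path: str) -> list[TranscriptionalUnit]:
    """Read transcriptional units from GTF exon (and optional transcript) rows.

    Exons are grouped by ``transcript_id`` and sorted; the declared transcript
    span, when present, must contain all of its exons.  Unstranded transcripts
    are rejected.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    spans: dict[str, tuple[str, int, int, str]] = {}
    rpkm: dict[str, float] = {}
    order: list[str] = []
    for lineno, scaf, feature, start, end, strand, attrs in _read_gtf_rows(path):
        if feature not in ("exon", "transcript"):
            continue
        tid = attrs.get("transcript_id")
        if not tid:
            raise FormatError(f"line {lineno}: missing transcript_id")
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: unstranded transcript {tid!r}")
        if "RPKM" in attrs:
            try:
                rpkm[tid] = float(attrs["RPKM"])
            except ValueError:
                raise FormatError(f"line {lineno}: bad RPKM value") from None
        if feature == "transcript":
            spans[tid] = (scaf, start, end, strand)
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
        else:
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
            exons[tid].append(GenomicInterval(scaf, start, end, strand))

    tus = []
    for tid in order:
        exs = exons[tid]
        if not exs:
            raise FormatError(f"transcript {tid!r} has no exon features")
        if tid in spans:
            scaf, s, e, strand = spans[tid]
            for ex in exs:
                if ex.scaffold_id != scaf or ex.start < s or ex.end > e:
                    raise FormatError(
                        f"transcript {tid!r}: exon [{ex.start}, {ex.end}) outside "
                        f"declared span [{s}, {e})"
                    )
        tus.append(
            TranscriptionalUnit.from_exons(
                tid, exs, exs[0].strand, expression_rpkm=rpkm.get(tid, 0.0)
            )
        )
    tus.sort(key=lambda t: (t.interval.sort_key(), t.tu_id))
    return tus


def write_tu_gtf(
    tus: Iterable[TranscriptionalUnit], path: str, provenance: Optional[str] = None
) -> None:
    tus = sorted(tus, key=lambda t: (t.interval.sort_key(), t.tu_id))
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for tu in tus:
            attrs = _fmt_attrs(
                [
                    ("gene_id", tu.tu_id),
                    ("transcript_id", tu.tu_id),
                    ("RPKM", f"{tu.expression_rpkm:.6g}"),
                ]
            )
            iv = tu.interval
            fh.write(
                f"{iv.scaffold_id}\ttbone\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in tu.exons:
                fh.write(
                    f"{ex.scaffold_id}\ttbone\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_gtf(
    genes: Iterable[GeneModel], path: str, provenance: Optional[str] = None
) -> None:
    """Write gene models as GTF with evidence attributes."""
    genes = sorted(genes, key=lambda g: (g.interval.sort_key(), g.gene_id))
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for g in genes:
            pairs = [
                ("gene_id", g.gene_id),
                ("transcript_id", g.gene_id),
                ("parent_tu", g.parent_tu_id),
                ("has_sl", "1" if g.has_sl_5p else "0"),
                ("has_polya", "1" if g.has_polya_3p else "0"),
                ("class", g.classification),
            ]
            if g.sl_summit is not None:
                pairs.append(("sl_summit", str(g.sl_summit)))
            if g.polya_summit is not None:
                pairs.append(("polya_summit", str(g.polya_summit)))
            if g.notes:
                pairs.append(("notes", g.notes))
            attrs = _fmt_attrs(pairs)
            iv = g.interval
            fh.write(
                f"{iv.scaffold_id}\ttbone\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.scaffold_id}\ttbone\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def read_gene_gtf(path: str) -> list[GeneModel]:
    """Read gene models written by :func:`write_gtf` (round-trip identity)."""
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for lineno, scaf, feature, start, end, strand, attrs in _read_gtf_rows(path):
        if feature != "exon":
            continue
        gid = attrs.get("transcript_id") or attrs.get("gene_id")
        if not gid:
            raise FormatError(f"line {lineno}: missing transcript_id")
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: unstranded transcript {gid!r}")
        if gid not in exons:
            order.append(gid)
            exons[gid] = []
            meta[gid] = attrs
        exons[gid].append(GenomicInterval(scaf, start, end, strand))
    genes = []
    for gid in order:
        attrs = meta[gid]
        sl = attrs.get("sl_summit")
        pa = attrs.get("polya_summit")
        exs = sorted(exons[gid], key=lambda e: e.start)
        iv = GenomicInterval(
            exs[0].scaffold_id, exs[0].start, exs[-1].end, exs[0].strand
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                parent_tu_id=attrs.get("parent_tu", gid),
                interval=iv,
                exons=exs,
                has_sl_5p=attrs.get("has_sl") == "1",
                has_polya_3p=attrs.get("has_polya") == "1",
                sl_summit=int(sl) if sl is not None else None,
                polya_summit=int(pa) if pa is not None else None,
                classification=attrs.get("class", "NO_SL"),
                notes=attrs.get("notes", ""),
            )
        )
    genes.sort(key=lambda g: (g.interval.sort_key(), g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, as-is)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str,
    names: Optional[list[str]] = None,
    provenance: Optional[str] = None,
) -> None:
    rows = list(intervals)
    if names is None:
        names = ["."] * len(rows)
    paired = sorted(zip(rows, names), key=lambda p: (p[0].sort_key(), p[1]))
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for iv, name in paired:
            fh.write(
                f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_repeat_bed(path: str) -> RepeatMask:
    return RepeatMask(read_bed(path))


def write_peaks_bed(
    peaks: Iterable[EvidencePeak], path: str, provenance: Optional[str] = None
) -> None:
    """Write peaks as BED6+2: name = kind, score = total_count, columns 7-8
    carry the summit as a half-open single-base interval."""
    peaks = sorted(peaks, key=lambda p: (p.interval.sort_key(), p.kind))
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{p.kind}\t{p.total_count}\t"
                f"{iv.strand}\t{p.summit}\t{p.summit + 1}\n"
            )


def read_peaks_bed(path: str) -> list[EvidencePeak]:
    """Read peaks written by :func:`write_peaks_bed`.

    Plain BED6 is accepted; without summit columns the 5'-most position in
    transcript orientation is used as the summit.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"line {lineno}: expected >= 6 columns for peaks")
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[5])
            if len(cols) >= 8:
                summit = int(cols[6])
            else:
                summit = iv.start if iv.strand == "+" else iv.end - 1
            out.append(
                EvidencePeak(
                    kind=cols[3], interval=iv, summit=summit, total_count=int(cols[4])
                )
            )
    return out


# ---------------------------------------------------------------------------
# bedGraph / wiggle tracks


def write_bedgraph(
    track: EndSignalTrack, prefix: str, provenance: Optional[str] = None
) -> tuple[str, str]:
    """Write one bedGraph file per strand: ``<prefix>.plus.bedgraph`` and
    ``<prefix>.minus.bedgraph``.  Runs of equal counts are compressed."""
    paths = {}
    for strand, suffix in (("+", ".plus.bedgraph"), ("-", ".minus.bedgraph")):
        path = prefix + suffix
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"#{provenance}\n")
            scafs = sorted(
                scaf for (scaf, st) in track.counts if st == strand
            )
            for scaf in scafs:
                bucket = track.counts[(scaf, strand)]
                run_start = None
                run_end = None
                run_count = None
                for pos in sorted(bucket):
                    c = bucket[pos]
                    if run_start is not None and pos == run_end and c == run_count:
                        run_end += 1
                        continue
                    if run_start is not None:
                        fh.write(f"{scaf}\t{run_start}\t{run_end}\t{run_count}\n")
                    run_start, run_end, run_count = pos, pos + 1, c
                if run_start is not None:
                    fh.write(f"{scaf}\t{run_start}\t{run_end}\t{run_count}\n")
        paths[strand] = path
    return paths["+"], paths["-"]


def read_bedgraph(path: str, strand: str, kind: str = "SL") -> EndSignalTrack:
    """Read one strand's bedGraph into an :class:`EndSignalTrack`."""
    track = EndSignalTrack(kind)
    _read_bedgraph_into(path, strand, track)
    return track


def _read_bedgraph_into(path: str, strand: str, track: EndSignalTrack) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
            scaf, start, end, count = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            if count <= 0:
                continue
            for pos in range(start, end):
                track.add(scaf, strand, pos, count)


def read_bedgraph_pair(prefix: str, kind: str) -> EndSignalTrack:
    track = EndSignalTrack(kind)
    for strand, suffix in (("+", ".plus.bedgraph"), ("-", ".minus.bedgraph")):
        path = prefix + suffix
        if os.path.exists(path):
            _read_bedgraph_into(path, strand, track)
    return track


def read_wiggle_fixed_step(path: str, strand: str, kind: str = "SL") -> EndSignalTrack:
    """Read a fixedStep wiggle file (compatibility shim for wiggle tracks)."""
    track = EndSignalTrack(kind)
    scaf = None
    pos = 0
    step = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                try:
                    scaf = fields["chrom"]
                    pos = int(fields["start"]) - 1  # wiggle is 1-based
                    step = int(fields.get("step", 1))
                except (KeyError, ValueError):
                    raise FormatError(f"line {lineno}: bad fixedStep header") from None
                continue
            if scaf is None:
                raise FormatError(f"line {lineno}: data before fixedStep header")
            value = int(float(line))
            if value > 0:
                track.add(scaf, strand, pos, value)
            pos += step
    return track


# ---------------------------------------------------------------------------
# TSV tables


def read_expression_tsv(path: str) -> dict[str, float]:
    """Read ``tu_id<TAB>rpkm`` rows."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"line {lineno}: expected tu_id<TAB>value")
            try:
                out[cols[0]] = float(cols[1])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric value") from None
    return out


def write_expression_tsv(
    values: dict[str, float], path: str, provenance: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        for key in sorted(values):
            fh.write(f"{key}\t{values[key]:.6g}\n")


read_counts_tsv = read_expression_tsv  # same layout, integer-valued


def validate_against_genome(
    intervals: Iterable[GenomicInterval], genome: dict[str, str] | list[GenomeSequence]
) -> None:
    """Raise :class:`ValidationError` for intervals outside scaffold bounds."""
    if not isinstance(genome, dict):
        genome = {g.scaffold_id: g.sequence for g in genome}
    for iv in intervals:
        if iv.scaffold_id not in genome:
            raise ValidationError(f"unknown scaffold {iv.scaffold_id!r}")
        if iv.end > len(genome[iv.scaffold_id]):
            raise ValidationError(
                f"interval [{iv.start}, {iv.end}) overflows scaffold "
                f"{iv.scaffold_id} (length {len(genome[iv.scaffold_id])})"
            )
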