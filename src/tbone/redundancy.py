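"""Nucleotide-level redundancy clustering and exact ORF deduplication.

Transcripts are clustered greedily at 95% global nucleotide identity
(identity = identical aligned bases / length of the shorter sequence), the
longest sequence founding each cluster — the conventional semantics of
greedy incremental clustering with ``-r 0 -c 0.95`` (no reverse-complement
comparison).  Clustered transcripts share a name prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .alignment import identity_over_shorter
from .errors import ParameterError, ValidationError

DEFAULT_IDENTITY_THRESHOLD = 0.95
DEFAULT_PREFILTER_K = 10


@dataclass
class ClusterAssignment:
    """member_id -> (representative_id, identity to the representative)."""

    assignment: dict[str, tuple[str, float]] = field(default_factory=dict)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member, (rep, _) in self.assignment.items():
            out.setdefault(rep, []).append(member)
        for members in out.values():
            members.sort()
        return out

    def n_clusters(self) -> int:
        return len({rep for rep, _ in self.assignment.values()})


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prefilter_passes(
    short: str, long_len: int, long_kmers: set[str], threshold: float, k: int
) -> bool:
    """Lossless shared-k-mer screen.

    If the global identity (matches / len(short)) is >= threshold, the
    alignment contains m >= ceil(t*L) match columns.  Maximal runs of match
    columns are contiguous in *both* sequences, so a run of length r yields
    r-k+1 k-mers present verbatim in both.  A run can only be interrupted by
    a non-match position of the shorter sequence (at most L - m) or by a gap
    column consuming the longer sequence (at most M - m), so there are at
    most L + M - 2m + 1 runs, and at least m - (k-1)(L + M - 2m + 1)
    positions of the shorter sequence carry a k-mer found in the longer one.
    Below that bound the pair is provably under threshold and is skipped
    without aligning.
    """
    L = len(short)
    if L < k:
        return True  # too short to screen
    m = math.ceil(threshold * L)
    bound = m - (k - 1) * (L + long_len - 2 * m + 1)
    if bound <= 0:
        return True
    shared = sum(
        1 for i in range(L - k + 1) if short[i : i + k] in long_kmers
    )
    return shared >= bound


def cluster_nt(
    seqs: dict[str, str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    prefilter: bool = True,
    prefilter_k: int = DEFAULT_PREFILTER_K,
) -> ClusterAssignment:
    """Greedy incremental clustering at a global nucleotide identity threshold.

    Sequences are visited longest-first (ties by id); each joins the first
    existing representative (founding order) reached at or above the
    threshold, else founds a new cluster.  Reverse-complement comparison is
    disabled.
    """
    if not (0.5 < identity_threshold <= 1.0):
        raise ParameterError(f"identity threshold {identity_threshold} outside (0.5, 1]")
    for sid, seq in seqs.items():
        if not seq:
            raise ValidationError(f"empty sequence {sid!r}")
    order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
    reps: list[str] = []
    rep_kmers: list[set[str]] = []
    result = ClusterAssignment()
    for sid in order:
        seq = seqs[sid].upper()
        placed = False
        for idx, rep in enumerate(reps):
            rep_seq = seqs[rep].upper()
            if prefilter and not _prefilter_passes(
                seq, len(seqs[rep]), rep_kmers[idx], identity_threshold, prefilter_k
            ):
                continue
            ident = identity_over_shorter(seq, rep_seq)
            if ident >= identity_threshold:
                result.assignment[sid] = (rep, ident)
                placed = True
                break
        if not placed:
            reps.append(sid)
            rep_kmers.append(_kmer_set(seq, prefilter_k) if prefilter else set())
            result.assignment[sid] = (sid, 1.0)
    return result


def dedupe_orf_aa(
    proteins: dict[str, str], transcript_lengths: Optional[dict[str, int]] = None
) -> tuple[set[str], dict[str, str]]:
    """Exact amino-acid deduplication of ORFs.

    Returns the non-redundant id set and a mapping id -> kept id.  Among
    identical proteins the kept id is the one with the longest source
    transcript (protein length when no lengths are given), ties by id.
    """
    groups: dict[str, list[str]] = {}
    for pid, aa in proteins.items():
        groups.setdefault(aa, []).append(pid)

    def source_len(pid: str) -> int:
        if transcript_lengths is not None:
            return transcript_lengths.get(pid, 0)
        return len(proteins[pid])

    kept: set[str] = set()
    mapping: dict[str, str] = {}
    for aa, ids in groups.items():
        winner = sorted(ids, key=lambda i: (-source_len(i), i))[0]
        kept.add(winner)
        for i in ids:
            mapping[i] = winner
    return kept, mapping


def assign_cluster_names(
    assignment: ClusterAssignment, prefix: str = "G", width: int = 6
) -> dict[str, str]:
    """Deterministic cluster-aware names ``<prefix><cluster#>.g<member#>``.

    Clusters are numbered by sorted representative id; members are numbered
    with the representative first, remaining members in sorted id order.  The
    mapping is bijective.
    """
    names: dict[str, str] = {}
    clusters = assignment.clusters()
    for cnum, rep in enumerate(sorted(clusters), start=1):
        members = [rep] + [m for m in clusters[rep] if m != rep]
        for gnum, member in enumerate(members, start=1):
            names[member] = f"{prefix}{cnum:0{width}d}.g{gnum}"
    return names
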