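"""Thin wrappers around edlib global alignment used across the toolkit."""

from __future__ import annotations

import re

import edlib

from .errors import ValidationError

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _align_stats(a: str, b: str) -> tuple[int, int]:
    """Global (NW) alignment of two sequences: (matches, alignment columns).

    Arguments are canonicalized (shorter/lexicographically smaller first) so
    the statistic is symmetric: co-optimal alignment paths returned by the
    aligner can otherwise differ by a match or two with argument order.
    """
    if (len(a), a) > (len(b), b):
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def identity_over_shorter(a: str, b: str) -> float:
    """Identical aligned bases divided by the length of the shorter sequence.

    This is the conventional semantics of greedy incremental clustering tools'
    identity threshold.
    """
    if not a or not b:
        raise ValidationError("cannot align empty sequence")
    matches, _ = _align_stats(a, b)
    return matches / min(len(a), len(b))


def identity_over_columns(a: str, b: str) -> tuple[float, int]:
    """Identity as matches / alignment columns, plus the column count."""
    if not a or not b:
        raise ValidationError("cannot align empty sequence")
    matches, columns = _align_stats(a, b)
    return matches / columns, columns
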