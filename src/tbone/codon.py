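"""Codon weight matrices and codon-optimized CDS design for transgenes.

A codon weight matrix holds per-codon relative adaptiveness: the count of a
codon among the most abundantly expressed non-redundant genes divided by the
count of the most-used synonymous codon for the same amino acid (so every
amino-acid family has a weight-1.0 codon).  Optimization emits, per residue,
the weight-1.0 codon, producing a fixed codon-optimized coding sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .orfs import CODON_TO_AA, STOP_CODONS

DEFAULT_TOP_N = 100

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

SENSE_CODONS = sorted(CODON_TO_AA)  # 61 codons


@dataclass
class CodonWeightMatrix:
    """Relative-adaptiveness weights for the 61 sense codons."""

    weight: dict[str, float]
    counts: dict[str, int]
    stop_codon: str
    source_gene_ids: list[str] = field(default_factory=list)

    def best_codon(self, aa: str) -> str:
        """The weight-1.0 codon for an amino acid (ties break alphabetically)."""
        codons = AA_TO_CODONS.get(aa)
        if not codons:
            raise ValidationError(f"unknown residue {aa!r}")
        best = max(self.weight[c] for c in codons)
        return min(c for c in codons if self.weight[c] == best)

    def to_rows(self) -> list[tuple[str, str, int, float]]:
        return [
            (c, CODON_TO_AA[c], self.counts.get(c, 0), self.weight[c])
            for c in SENSE_CODONS
        ]


def _validate_cds(gene_id: str, cds: str) -> None:
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS {gene_id!r}: length not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValidationError(f"CDS {gene_id!r}: does not start with ATG")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in STOP_CODONS:
        raise ValidationError(f"CDS {gene_id!r}: does not end with a stop codon")
    for j, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValidationError(f"CDS {gene_id!r}: internal stop at codon {j}")
        if c not in CODON_TO_AA:
            raise ValidationError(f"CDS {gene_id!r}: invalid codon {c!r}")


def build_weight_matrix(
    cds: dict[str, str],
    expression: dict[str, float],
    top_n: int = DEFAULT_TOP_N,
) -> CodonWeightMatrix:
    """Count codon usage over the ``top_n`` most expressed genes and derive
    relative-adaptiveness weights.

    Codon counts exclude the terminal stop (stop usage is tallied separately
    to pick the emitted stop codon).  Unobserved codons in an observed family
    get a pseudo-weight of 0.5 / max-count so they are representable but never
    chosen; a fully unobserved family gets uniform weight 1.0 (flagged by a
    warning).  Only expression ranks matter, not the scale.
    """
    for gid, seq in cds.items():
        _validate_cds(gid, seq.upper())
    ranked = sorted(cds, key=lambda g: (-expression.get(g, 0.0), g))
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} genes available for a top-{top_n} matrix; using all",
            stacklevel=2,
        )
    selected = ranked[:top_n]

    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    stop_counts: dict[str, int] = {c: 0 for c in sorted(STOP_CODONS)}
    for gid in selected:
        seq = cds[gid].upper()
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        stop_counts[codons[-1]] += 1
        for c in codons[:-1]:
            counts[c] += 1

    weight: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        mx = max(counts[c] for c in codons)
        if mx == 0:
            warnings.warn(f"amino acid {aa} unobserved; uniform weights", stacklevel=2)
            for c in codons:
                weight[c] = 1.0
            continue
        for c in codons:
            weight[c] = counts[c] / mx if counts[c] > 0 else 0.5 / mx

    best_stop = max(stop_counts.values())
    stop_codon = min(c for c, n in stop_counts.items() if n == best_stop)
    return CodonWeightMatrix(
        weight=weight, counts=counts, stop_codon=stop_codon, source_gene_ids=selected
    )


def _looks_like_cds(s: str) -> bool:
    return (
        len(s) >= 6
        and len(s) % 3 == 0
        and set(s) <= set("ACGT")
        and s.startswith("ATG")
    )


def optimize_cds(
    protein_or_cds: str,
    matrix: CodonWeightMatrix,
    mode: str = "max_weight",
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Emit a codon-optimized CDS for a protein (or a translatable CDS).

    ``max_weight`` (default) picks the weight-1.0 codon per residue, ties
    alphabetical — deterministic, idempotent, and translation-preserving.
    ``sample`` draws synonymous codons proportionally to their weights with a
    caller-supplied seeded generator.  The most frequent observed stop codon
    is appended.
    """
    s = protein_or_cds.upper().strip("*")
    if _looks_like_cds(s):
        from .orfs import translate_cds

        protein = translate_cds(s)
    else:
        protein = s
    if not protein:
        raise ValidationError("empty protein")
    out = []
    for aa in protein:
        codons = AA_TO_CODONS.get(aa)
        if not codons:
            raise ValidationError(f"unknown residue symbol {aa!r}")
        if mode == "max_weight":
            out.append(matrix.best_codon(aa))
        elif mode == "sample":
            if rng is None:
                raise ValidationError("sample mode requires a seeded generator")
            w = np.array([matrix.weight[c] for c in codons], dtype=float)
            out.append(codons[rng.choice(len(codons), p=w / w.sum())])
        else:
            raise ValidationError(f"unknown mode {mode!r}")
    return "".join(out) + matrix.stop_codon


def write_matrix_tsv(matrix: CodonWeightMatrix, path: str, provenance=None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"#{provenance}\n")
        fh.write("codon\taa\tcount\tweight\n")
        for codon, aa, count, weight in matrix.to_rows():
            fh.write(f"{codon}\t{aa}\t{count}\t{weight:.6g}\n")
        fh.write(f"{matrix.stop_codon}\t*\t-\t1\n")


def read_matrix_tsv(path: str) -> CodonWeightMatrix:
    weight: dict[str, float] = {}
    counts: dict[str, int] = {}
    stop_codon = "TAA"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("codon\t"):
                continue
            codon, aa, count, w = line.split("\t")
            if aa == "*":
                stop_codon = codon
                continue
            weight[codon] = float(w)
            counts[codon] = int(count)
    return CodonWeightMatrix(weight=weight, counts=counts, stop_codon=stop_codon)
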