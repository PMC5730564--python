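"""Cluster redundant transcripts and design a codon-optimized transgene CDS.

Transcripts at >= 95% global nucleotide identity (identity = identical
aligned bases / shorter length; no reverse-complement comparison) share a
name prefix.  A codon weight matrix built from the most-expressed genes then
emits a fixed codon-optimized coding sequence for a given protein.
"""

import numpy as np

from tbone import (
    assign_cluster_names,
    build_weight_matrix,
    cluster_nt,
    optimize_cds,
    translate_cds,
)
from tbone.codon import AA_TO_CODONS

rng = np.random.default_rng(4)
bases = np.array(list("ACGT"))
base_seq = "".join(bases[rng.integers(0, 4, size=900)])
variant = list(base_seq)
for p in rng.choice(900, size=20, replace=False):  # ~97.8% identity
    variant[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[p]]
seqs = {
    "tx1": base_seq,
    "tx2": "".join(variant),
    "tx3": "".join(bases[rng.integers(0, 4, size=700)]),
}
assignment = cluster_nt(seqs, identity_threshold=0.95)
names = assign_cluster_names(assignment, prefix="G")
print(f"{len(seqs)} transcripts -> {assignment.n_clusters()} clusters")
for member in sorted(names):
    rep, ident = assignment.assignment[member]
    print(f"  {member} -> {names[member]} (rep {rep}, identity {ident:.3f})")

# codon matrix from synthetic highly expressed genes
cds, expr = {}, {}
for i in range(120):
    codons = []
    for aa, fam in sorted(AA_TO_CODONS.items()):
        codons.append(fam[int(rng.integers(0, len(fam)))])
    cds[f"g{i:03d}"] = "ATG" + "".join(codons) + "TAA"
    expr[f"g{i:03d}"] = float(rng.uniform(0.1, 100))
matrix = build_weight_matrix(cds, expr, top_n=100)
optimized = optimize_cds("MSKGEELFTGVV", matrix)
print(f"optimized CDS for MSKGEELFTGVV: {optimized}")
print(f"translates back: {translate_cds(optimized)}")
# Per residue the weight-1.0 (most-used) codon is emitted, so the output is
# deterministic, idempotent, and translation-preserving.
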