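# Methods

This note documents the models, parameters and numerical choices behind the
toolkit, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Coordinates and formats

All in-memory intervals are 0-based half-open on named scaffolds.  GTF
(1-based inclusive) and BED/bedGraph (0-based half-open) conversion happens
only in `tbone.io_formats`, so there is exactly one place where an off-by-one
could live.  Strand `.` is permitted only for repeats and duplication-block
intervals.  Signal tracks are written as per-strand bedGraph pairs
(`.plus.bedgraph` / `.minus.bedgraph`); a fixedStep wiggle reader is provided
for compatibility with wiggle-producing mappers.  Evidence peaks are exported
as BED6 (name = kind, score = total count) plus two extra columns carrying
the summit — plain BED6 is accepted back, with the 5′-most position used as
the summit fallback.  All writers sort records and emit no timestamps, so
identical inputs give byte-identical files; provenance headers carry the tool
version and a configuration hash only.

## Evidence extraction

**SL detection.** A read is SL evidence iff a 3′ suffix of the leader, of
length ≥ `min_match` (default 10), matches the read prefix with ≤
`max_mismatch` (default 1) mismatches; the longest such suffix is trimmed.
Only leader *suffixes* are considered because the trans-splice junction joins
the leader's 3′ end to the acceptor site.  Reads shorter than 20 nt after
trimming are unusable for mapping and are returned untagged.  The leader
sequence is organism-specific and is required input.

**Poly(A) detection.** A trailing A-run with ≤ `max_non_a` (default 1)
interruptions and ≥ `min_a_run` (default 5) A's is trimmed.  Reads from
T-fill-style 3′-end protocols end at the cleavage site by construction, so
`assume_tfill=True` tags them regardless of a residual tail.

**Pileup and peaks.** Mapped biological end positions (from BED, or SAM with
soft-clips ignored: SL position = alignment start on `+` / end − 1 on `-`,
poly(A) the opposite end) accumulate into strand-specific per-base tracks.
The notion of a "signal peak" is deliberately simple and deterministic:
positions on one (scaffold, strand) are grouped into runs with gaps ≤
`merge_distance` (default 10 nt), and a run is a peak iff its total count ≥
`min_site_count` (default 5).  The summit is the highest-count position; ties
break toward the transcript 5′ direction, which yields the longest mature
mRNA — the conservative choice for promoter selection.  Grouping conserves
counts (peaks + sub-threshold groups = track total) and is monotone in
`min_site_count`; on jitterless data every planted site is its own summit, so
recovery is exact.

## Cutting (boundary assignment)

Peaks are assigned to every same-strand TU whose span, padded by `end_slack`
(default 50 nt), contains the summit; multi-TU assignments are reported.  The
pad exists because assemblers under-assemble UTR ends: evidence slightly
outside the model should extend it, not be lost.

Cutting runs in *oriented* coordinates (minus-strand positions are reflected
as `p → -(p+1)`), which makes strand symmetry — cutting commutes with
reflection — true by construction rather than by case analysis.  With SL
summits `s₁ < … < s_k` (transcript orientation):

* gene *i* starts at `s_i` and ends at the strongest poly(A) summit strictly
  between `s_i` and `s_{i+1}` (ties: 5′-most, i.e. strongest-and-proximal
  wins; alternative 3′ ends are not emitted as extra models);
* with no poly(A) summit in the segment the gene runs to `s_{i+1}` (or the TU
  3′ end) and `has_polya_3p` is false;
* a 5′ leader segment before `s₁` longer than `min_gene_len` is emitted
  without SL evidence;
* `k = 0`: the TU becomes one `NO_SL` gene.  If poly(A) evidence exists its
  3′ end is set to the strongest summit (keeping the invariant that a
  poly(A)-flagged model ends at its summit); with no evidence at all the TU
  is returned unchanged.

Summits falling inside parent introns are snapped to the nearest exonic base
3′ of them (SL) or 5′ of them (poly(A)), and the move is recorded in the
model's `notes`.  Exons are clipped to each gene span; models with clipped
exonic length < `min_gene_len` (default 100 nt, generous against the shortest
transcripts such assemblies retain) are dropped.  Classification is per
parent: one SL summit → `SL_SINGLE`, several → `SL_MULTIPLE_PARENT` (a
polycistronic precursor), none → `NO_SL`.

## Filters

**Antisense.** For every opposite-strand TU pair with exonic overlap covering
≥ `min_overlap_frac` (default 0.5) of the lower-expressed transcript's exonic
length, the lower-count transcript is discarded when the strand-specific
read-count ratio is ≥ 5.0 ("at least fivefold" read inclusively).  A zero
count on one side makes the ratio infinite; two zero counts give no evidence
of a difference and both survive.  All decisions use the original counts, so
the filter is idempotent and a discarded transcript cannot rescue another.

**Low expression.** A TU is discarded iff RPKM < 0.5 (strict) *and* it does
not overlap a trusted reference mapping.  RPKM uses the standard formula
`reads × 10⁹ / (length × total mapped reads)`.

## ORF tools

`find_longest_orf` scans the three forward frames only (gene models are
stranded mature mRNAs) and considers complete candidates — ATG to the first
in-frame stop — returning the longest with ≥ `min_aa` (default 100, the
conventional coding-potential cutoff) residues, ties to the 5′-most start.
No Markov coding score or homology evidence is used.

`merge_split_transcripts` repairs models broken across repeats: for adjacent
same-strand fragments (A upstream in transcript orientation), merge iff A has
an ORF but no poly(A) site, B has a poly(A) site but no ORF, the genomic gap
between facing ends is ≤ 10 kb, and the repeat mask covers ≥
`min_repeat_frac` (default 0.5) of the gap (an empty gap counts as covered;
"repetitive span" is not otherwise binary-defined).  Merging is a single
5′→3′ pass; chains of three or more fragments merge only if the conditions
re-hold after each step.  The gap becomes an intron, the ORF is re-called on
the merged transcript when the genome is available, and both pre- and
post-merge ORFs are recorded in the merge report.

## Redundancy clustering

Greedy incremental clustering: sequences sorted longest-first (ties by id)
either join the first representative (founding order) at identity ≥ 0.95 or
found a new cluster.  Identity is identical aligned bases over the shorter
sequence's length from a global (Needleman–Wunsch, via edlib) alignment;
reverse-complement comparison is disabled.  Because co-optimal alignment
paths can differ by a match or two depending on argument order, alignments
are computed in a canonical argument order so identity is symmetric.

A lossless shared-k-mer prefilter (k = 10) skips hopeless alignments: if
identity ≥ t, the alignment has `m ≥ ⌈tL⌉` match columns (L = shorter
length), and match runs — contiguous in both sequences — are interrupted at
most `L + M − 2m` times, so at least `m − (k−1)(L + M − 2m + 1)` shorter-
sequence positions carry a k-mer present in the longer sequence.  Pairs below
this bound are provably under threshold.  The bound degrades to pass-through
for very unequal lengths, which is exactly when it is unsafe.

ORF deduplication is exact amino-acid string identity; the kept id is the
longest source transcript (ties lexicographic).  Cluster-aware names follow
`<prefix><cluster#>.g<member#>` with the representative as member 1, so
related transcripts share a prefix and naming is bijective and deterministic.

## Codon tools

The weight matrix counts codons (terminal stops tallied separately) over the
`top_n = 100` most-expressed genes (non-redundant selection is the
redundancy module's job, upstream).  `w(c) = n(c) / max` over the synonymous
family, so every family has a weight-1.0 codon; unobserved codons in an
observed family get `0.5 / max` — representable, never chosen; a fully
unobserved family falls back to uniform weights with a warning.  Only
expression *ranks* matter.  Optimization is deterministic: per residue the
weight-1.0 codon (ties alphabetical), plus the most frequent observed stop —
fixed sequences are what transgene synthesis needs.  A seeded
weighted-sampling mode exists but is not the default.  Restriction-site
avoidance and GC balancing are out of scope.

## Duplication scan

Repeat-masked positions become N.  Exact k-mer anchors (k = 16; k-mers
occurring > 50 times are skipped as unmasked high-copy sequence) between
distinct loci are grouped per (scaffold pair, orientation, diagonal) and
chained with a 100-nt gap limit; at 95% identity the expected spacing between
exact 16-mers is ~13 nt, so chains span whole blocks with overwhelming
probability.  Chains are extended outward by exact matching only — the chain
already covers a block's interior, and stopping at the first mismatch keeps
boundaries deterministic.  Candidate locus pairs are then globally aligned
(edlib) and reported iff aligned length > 500 (strict) and identity —
matches over alignment columns — is ≥ 0.95.  Pairs whose intervals overlap
are tandem self-hits and are discarded; mirror duplicates are removed by
canonical interval ordering, and near-duplicate candidates by reciprocal-
overlap containment.  `duplicated_fraction` counts the union of block-covered
positions, optionally excluding masked bases.

## The synthetic-data generator

The generator emulates the inputs a boundary-annotation run consumes: random
multi-scaffold genomes; strand-assigned TUs with 1–3 genes of 1–3 exons each
(gene spans ~450–1350 nt, introns 80–250 nt, exonic inter-gene spacers
150–300 nt); per-site read counts Poisson(20); optional Gaussian positional
jitter and per-base read errors (defaults 0 — the clean, exactly recoverable
regime); a 20% no-evidence TU class; antisense TUs planted over 20% of
evidence TUs at an exact count ratio (default 5.0, the filter threshold);
repeats covering 5% of each scaffold; and planted duplications with an exact
number of substitutions (`round(L·(1−identity))`) and deliberately
mismatching flanking bases, so each planted block has sharp, well-defined
boundaries against which the scan's decisions can be scored binarily.

Each output file draws from its own seed-derived stream, so adding an output
never perturbs the others, and a fixed seed reproduces every file
byte-for-byte.  What it does **not** emulate: mapping ambiguity and
multi-mappers, base-quality models, internal priming artifacts at A-rich
sites, indel divergence in duplications, alternative splicing, and overlapping
same-strand genes.  Passing tests therefore demonstrate the correctness of
the algorithms under their stated models, not robustness to every artifact of
real libraries.

Layout note: TUs occupy the first 55% of each scaffold, repeats the next 25%,
duplications the rest; infeasible packings (too many TUs, too many planted
duplications) raise a configuration error rather than silently overlapping.

## Problem sizes and determinism

The test suite and the acceptance script run on 20–50-TU genomes (4 × 150 kb
scaffolds, ~1,600 evidence reads), 10-seed jitter sweeps, 1,000-sequence ORF
and protein panels, 50-sequence clustering sets and a 30-point duplication
grid (lengths 300–800 nt × identities 0.90–1.00, both orientations) — sizes
chosen so every check is exact or high-powered while a full run stays in the
minutes range on one CPU.  All randomness flows through explicit seeds; the
pipeline writes no timestamps, so reruns are byte-identical.

## Known limitations

* Peak calling has no local-background model; a site buried inside another
  peak's merge window is absorbed into it.
* A poly(A) summit is claimed by one gene (strongest-in-segment); genuinely
  shared 3′ ends between tandem genes are resolved by position, not by
  read assignment.
* Clustering identity (global alignment over the shorter length) can exceed
  the threshold for sequences of very different lengths; coverage constraints
  of specialised clustering tools are intentionally not reproduced.
* The duplication scan assumes substitution-style divergence; heavily
  indel-diverged duplications fragment across diagonals and may be missed or
  reported piecewise.
* The merge step trusts upstream ORF calls; a spurious ORF in A or a missed
  ORF in B changes the merge decision.
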