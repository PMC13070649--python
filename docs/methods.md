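# Methods

This note documents the models and algorithms inside `umiamp`, the
parameters that matter, the design decisions that were genuinely open, and
what the simulator does and does not emulate.

## UMI extraction

A dual-UMI amplicon construct is modelled as

```
fwd_anchor + fwd_umi + insert + revcomp(rev_umi) + revcomp(rev_anchor)
```

Anchors are located by **semi-global alignment** (anchor aligned end to
end, free gaps at the window boundaries, unit costs for mismatch,
insertion, deletion) within a `terminal_window` (default 200 bp) at each
read end.  The alignment is an explicit dynamic program vectorised over the
window axis; ties in the minimum distance are broken toward the smallest
anchor end position, so results are deterministic and exactly reproducible
by a brute-force oracle.  Unit costs without affine gaps are adequate at
the ≤ ~10% read error rates of current nanopore chemistry; the anchor
search is not the accuracy bottleneck.

Both read orientations are scored (forward anchor at the head of the read
and of its reverse complement); the hypothesis with the lower total anchor
edit distance wins, ties going to the plus orientation.  The UMI is
harvested as exactly `umi_length` bases adjacent to the anchor end — there
is no secondary alignment of the UMI itself; the IUPAC pattern check is the
only UMI-level validation.  The canonical UMI
`fwd_umi + revcomp(rev_umi)` is invariant under reverse complement of the
read, which is what makes strand-mixed clustering possible.

Gates are applied in the order length → anchor → pattern, and failures are
statuses, never exceptions.  Defaults: `max_anchor_edits` 3,
`max_pattern_mismatches` 2 (summed over both arms), `terminal_window`
200.  These are this package's own conservative defaults, exposed in the
configuration; tighten the pattern gate for designs with many constrained
(non-N) positions.

A consequence worth knowing: at 5% per-base read error, roughly a third of
reads fail the pattern gate, mostly because an indel inside a UMI arm
frame-shifts the constrained IUPAC positions.  This is intended behaviour
— those UMIs are unreliable — but it means read budgets should be planned
at roughly 2× the wanted per-cluster coverage.

## Two-step clustering

Step 1 is classic greedy abundance-sorted centroid clustering on canonical
UMIs: identical UMIs are grouped; groups are visited in descending
abundance (ties lexicographic); each group joins the first existing
cluster whose centroid is within `max_edit_dist_step1` (default 3) or
founds a new cluster.  Centroids never move.  The explicit ordering makes
the output invariant under any permutation of the input reads.

Clusters below `min_reads_per_cluster` (default 10) are discarded, then
step 2 summarises each surviving cluster by a column-majority consensus
UMI (canonical UMIs are fixed-length, so no MSA is needed; ties keep the
centroid base) and re-clusters these summaries at `max_edit_dist_step2`
(default 2), weighting each by cluster size.  Co-clustered step-1 clusters
are merged with provenance (`parent_ids`).  The second pass absorbs
satellite clusters founded by error-bearing copies of an abundant
molecule's UMI — the failure mode that a single greedy pass leaves behind.

Edit distances are computed with `edlib` (bounded Levenshtein); the test
suite checks the primitive against an independent full-matrix DP oracle.

Subsampling to `max_reads_per_cluster` (default 60) is uniform without
replacement and deterministic under (seed, cluster_id).  Quality-weighted
read selection was deliberately not implemented: it would couple cluster
membership to basecaller calibration, and uniform sampling keeps the
pipeline testable bit-for-bit.

Known limitation: with a 36 bp canonical UMI at 5% per-base error, about
10% of harvested UMIs land more than 3 edits from their molecule's true
UMI.  Those reads found satellites that are usually below
`min_reads_per_cluster` and are dropped, so molecules near the size
threshold can fall just under it.  Clustering *accuracy* is unaffected
(adjusted Rand index ≈ 1 against simulator truth); cluster *yield* is what
absorbs the UMI read errors.

## Consensus polishing

Two strategies, selected per run:

**POA (reference-free).**  Reads are aligned one at a time against a
partial order graph by global DP over the topological order (match +2,
mismatch −2, gap −2).  Matching bases fuse with existing nodes, mismatches
and insertions add nodes, and every read contributes a start→end path;
node and edge weights count traversing reads.  Traceback is deterministic
(match > deletion > insertion; among predecessors: higher weight, then
smaller node id).  Reads are added in descending length order (ties
lexicographic) because POA output is order-sensitive and the longest read
provides the most stable backbone.  The consensus is the
**maximum-total-edge-weight** start→end path.  Edge weights — not node
weights — are the correct objective: a detour through a node supported by
one erroneous read adds that node's weight but forfeits the heavy direct
edge, so insertion errors are suppressed; a node-weight objective would
instead absorb every observed insertion.  Per-base support is node weight
divided by cluster size.

**Reference-based.**  Each read is globally aligned to the reference
amplicon (unit costs, via edlib; the CIGAR is expanded into pileup events)
and columns keyed (reference position, insertion rank) are voted: majority
base per column, ties toward the reference base; a gap majority deletes
the column; insertion columns are emitted only on a **strict majority** of
covering reads (ties toward gap), which suppresses the indel noise
dominant in nanopore data.  The result is permutation-invariant in the
read list.  This strategy is linear-time per read pair and is the default
whenever a reference exists (the common case in targeted sequencing); POA
remains available for reference-free applications.

Per-base support maps to a Phred-like quality
`q = round(−10·log10(max(1 − support, 1/(n+1))))` capped at 60; the
`1/(n+1)` floor encodes that n agreeing reads cannot attest an error
probability below ~1/(n+1).

Both strategies perform a single consensus pass per cluster.  Iterative
re-polishing (aligning reads back to the first-pass consensus) was left
out deliberately: on simulated data a single pass already reaches the Q40
regime at 30–50 reads per cluster, and a second pass would double the
dominant cost.

## Variant levels

Every consensus sequence is aligned to the reference with the same aligner
as reference-based polishing and contributes one allele per column; a
variant call is (position, ref allele, alt allele) with level =
alt_count / depth, emitted when level ≥ `min_level` (default 0.01) and
alt_count ≥ `min_alt_count` (default 3).  Because each consensus
represents one molecule, the level is a direct molecular frequency — no
error model beyond counting is needed, and at every column the allele
counts sum to the depth.  Indels are represented per alignment column
(deletion: alt `-`; insertion before position p: ref `-`), converted to
1-based anchored representation only in the human-facing TSV and the
minimal VCF 4.2 writer.

Set comparison keys variants by (pos, ref, alt): recall and precision over
the key sets, specificity over the declared number of callable
non-variant positions, F1 as the harmonic mean, and level agreement as the
squared Pearson correlation over shared variants (reported as missing with
fewer than two shared variants; an empty test set reports precision 0 with
a flag).  Binomial recovery checks use a normal-approximation 95% CI from
the call depth.

## Live monitoring and early stopping

Batch FASTQs are discovered by polling (manifest override available) and
folded into a per-sample incremental store: each passing read's canonical
UMI joins the nearest centroid within `max_edit_dist_step1` (ties to the
earliest-founded centroid) or founds a new one.  The reported cluster
count only includes clusters with ≥ `min_reads_per_cluster` reads —
without that floor, early counts are inflated by singletons.  Counts are
monotone non-decreasing over batches, and the run stops once **every**
sample reaches the threshold (boundary inclusive).

No global abundance sort is possible online, so the incremental clusters
drive only the stop decision; the offline two-step pass is re-run over the
accumulated reads before polishing.  Streaming assignment uses
nearest-centroid while the offline greedy pass uses first-within-threshold;
the two coincide whenever true UMIs are well separated relative to the
threshold (the designed operating regime) and the package makes no
equivalence claim outside it.

Batch files are processed in batch-index order interleaved across samples
(mirroring arrival order on a real instrument), so a multi-sample replay
never exhausts one sample before seeing the next.

## Simulator

The generator emulates the statistical structure the method assumes:

- unique dual UMIs drawn uniformly from the design's IUPAC pattern, with
  near-colliding canonical UMIs (< 4 edits apart) re-drawn so that
  cluster-recovery truth is unambiguous (a flag allows collisions for
  stress testing);
- PCR jackpotting as log-normal read multiplicity, default μ = ln 30,
  σ = 0.6, truncated to [1, 200] — a skewed cluster-size distribution with
  a realistic median for targeted UMI experiments;
- independent per-base errors at default rates 2.5% substitution, 1.25%
  insertion, 1.25% deletion (5% total, nanopore-like); uniform placement,
  no homopolymer awareness;
- strand mixture (default 50% reverse-complemented), optional variant
  haplotypes assigned multinomially at target levels, optional chimeric
  reads splicing two molecules;
- full ground truth (molecule table, read→molecule map, error counts) and
  byte-identical output under a fixed seed.

What it does **not** emulate: homopolymer-biased indels, quality-score
trajectories, adapter/barcode chemistry, PCR substitution errors shared
between reads of one molecule (jackpotting is modelled in multiplicity
only).  Passing tests therefore demonstrate correctness of the algorithms
under independent-error assumptions, not robustness to correlated
nanopore artefacts; the strict-majority insertion rule and the dual-UMI
pattern gate are the mechanisms expected to carry over to real data.

## Problem sizes and numerical choices

The bundled accuracy benchmark uses 100 molecules × 50 reads on a 500 bp
amplicon (≈ 5000 reads), where the mean consensus error of the
reference-based strategy is measured at 0.0% — comfortably inside the Q40
(< 0.01%) regime; the test suite exercises POA exactness at small scale
and both strategies' agreement on downstream variant calls.  Scaling is
asserted on algorithmic work counters (reads processed, alignment cells,
clusters polished) rather than wall-clock time: the counters are
hardware-independent, exactly reproducible, and linear in sample count by
construction of the per-sample pipeline.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; subsampling derives per-cluster seeds from
(seed, crc32(cluster_id)).  All output files use `\n` newlines, 6
significant digits for floats, and deterministic orderings (founding
order for clusters, (position, allele) for variants), so byte comparison
is a valid equality test and is used as such in the test suite.
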