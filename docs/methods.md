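# Methods

## Model

The package treats a read's median k-mer frequency (RMKF) as a proxy for
its locus's sequencing depth: if a locus is covered d-fold, each of its
k-mers is seen about d·(L−k+1)/L times per strand across the dataset, and
the median over a read's k-mers is robust to the handful of error k-mers a
cleaned read still carries. Counting is exact (a hash table), non-canonical
(forward and reverse-complement k-mers are distinct keys, so observed
counts are roughly half the two-strand depth), and windows containing an
ambiguous base contribute nothing.

Normalization is two-pass by design: one pass to count, one to bin and
select. This is deliberately not a streaming (diginorm-style) acceptance
rule — binning the whole set first is what makes targeted selection of the
most unique clusters and of two-sided mate pairs possible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 19 | k-mer size for counting and the minimum usable read length |
| cutoff (C) | — (required) | RMKF at or below which reads are always kept; ≈ half the desired output coverage because strands are counted separately |
| num_bins (Z) | 100 | retention bins; bin b keeps b % of its reads, bin Z keeps 100 % |
| identity | 0.90 | greedy clustering identity threshold |
| min_cov | 0.40 | required aligned fraction of the shorter sequence |
| seed | 0 | drives every shuffle; runs are bit-reproducible |

Bin assignment is ⌈(C/RMKF)·Z⌉ computed on exact rationals
(`fractions.Fraction`), so reads sitting exactly on a bin boundary —
RMKF = C, or (C·Z)/RMKF integer — are classified without float drift; the
boundary RMKF = C is inclusive (bin Z). Bin quotas use half-up rounding;
per-cluster ideals use ceiling, which guarantees progress on singleton
clusters and lets unfilled clusters roll their share into later, larger
ones. A bin that cannot fill its quota does **not** push the shortfall
into other bins: redistribution would distort the retention ratios the
bins encode.

## Selection order and randomness

One `random.Random(seed)` stream drives a run. Draw order is fixed: bin Z
is recruited wholesale first (toggling its members' mate status when
tracking), then bins ascending from 1; within a bin, clusters in
(size, representative-id) order; within a cluster or bin, ids are sorted
before shuffling. Mate-priority tie-breaks inside a tier are the shuffled
order. Identical inputs, configuration and seed therefore give
byte-identical selected-id lists on any platform.

With mate tracking, a cluster's two-sided pairs are taken as units while
two selection slots remain; a pair that no longer fits is re-queued as
one-sided candidates. Reads evaluated but not selected are marked
discarded, which is what demotes their surviving mates to fragment
priority later; reads removed by the input filter leave tombstones in the
pairing table with the same effect.

## Clustering

The intra-bin clustering is greedy and incremental in the cd-hit
tradition: reads sorted by descending length (id tie-break), each read
joins the first cluster whose representative it matches, else founds a new
cluster. The match predicate aligns the shorter sequence — both strands —
against the representative with edlib in infix mode (whole query, free
target ends) and takes identity = matches / alignment columns. This is the
shorter-sequence identity convention rather than a trimmed
Smith-Waterman local alignment; a trimmed alignment could pass a
high-identity sub-window of a pair whose overall identity is below 90 %,
blurring the threshold. The consequence is that co-clustering captures
containment and near-full-length similarity but not short dovetail
overlaps, so `min_cov` (aligned fraction of the shorter sequence) is 1.0
whenever a match exists; the parameter is kept for the contract and for
alternative backends. A shared exact 14-mer between read and
representative (either strand) is required before any alignment is
attempted; at a 90 % identity floor over ≥ 40 bp this prefilter is
effectively lossless and keeps clustering near-linear.

Bins are clustered independently (each bin is a depth stratum; clusters
rank uniqueness *within* that stratum), and no attempt is made to
reproduce cd-hit-est's word-filter heuristics or exact memberships — only
the thresholds and the greedy contract.

## Synthetic data

The generator emulates amplification-biased sequencing directly at the
coverage level: the genome (seeded i.i.d. bases at a chosen GC, optionally
with an exact two-copy repeat) is tiled into fixed windows, each with a
target depth, and read starts are drawn per window in proportion to that
depth. Profiles can be uniform, two-tier (e.g. 500×/10×), or log-normal
per-window multipliers with hard spike/trough overrides. Substitution
errors are i.i.d. per base; paired mode draws Gaussian inserts truncated
at the read length. Every read carries truth (origin, strand, window,
repeat flag), so window depth is computed exactly from truth — no aligner,
no downloads, fully deterministic.

What this does **not** model: the branching-process autocorrelation of
real MDA bias, platform-specific error profiles (homopolymers, quality
decay), chimeras, and adapter/contaminant artifacts. Passing tests
therefore demonstrate the selection machinery's behaviour under known
coverage bias, not robustness to raw-instrument noise — real inputs are
expected to be error-corrected upstream, which is also the regime the
method assumes (false low-frequency k-mers removed).

Problem sizes in the test and acceptance workloads (20–50 kb genomes,
100 bp reads, tens of thousands of reads, spikes at 200–500× against 3–10×
troughs) were chosen as the smallest instances that still separate the
depth tiers cleanly and exercise every bin/cluster/mate code path.

## Evaluation metrics

* **Window depth**: summed read-window overlap bases / window length, from
  simulation truth.
* **≥ 5-fold fraction**: fraction of windows at or above 5× (boundary
  inclusive) — the floor an assembler needs to extend consensus through a
  region.
* **Two-sided rate**: 2 · (pairs with both mates selected) / (selected
  reads that belong to any original pair). The denominator is selected
  pair-members, not all selected reads, so the metric compares selection
  strategies at equal read budget.
* **Depth ratio**: mean depth over high-tier windows / mean over low-tier
  windows; normalization should shrink it, bin-less random subsampling
  provably cannot.

## Degenerate inputs and edge rules

* k longer than every read: empty count table with a warning, not an
  error; all reads then filter out as zero-RMKF.
* Reads with no valid k-mer (all-N, too short): RMKF 0, removed with a
  recorded reason.
* Empty selection: output files are written empty (flag-controlled).
* `track_mates` on fragment-only input: warn and proceed as fragments.
* Even-length median lists: lower median, keeping RMKF integer-valued.

## Known limitations

* Clustering does not join reads whose only relation is a short (< full
  shorter-read) overlap; in deep bins this fragments position-shifted
  reads into more clusters than cd-hit-est would produce. Uniqueness
  ranking — the quantity that matters downstream — is insensitive to this
  granularity in practice.
* The RMKF depth proxy assumes a single genome; mixed samples normalize
  each organism separately and need taxonomic pre-binning.
* No automatic cutoff estimation from the k-mer spectrum; the cutoff is a
  user decision (guidance: half the desired output coverage).
* Exact hash-table counting holds the full k-mer set in memory; this is
  sized for single-genome projects, not metagenome-scale sketching.
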