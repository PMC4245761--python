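# kmernorm

Reference-free coverage normalization of shotgun sequencing reads by
median k-mer frequency binning.

## The problem

Random-primed amplification — multiple displacement amplification (MDA) of
single cells, or sequence-independent single-primer amplification (SISPA)
of viral samples — makes unculturable organisms sequenceable, but at the
cost of extreme coverage bias: some genomic windows end up covered
hundreds-fold while neighbouring windows get almost nothing.
Overlap-layout-consensus assemblers want 40–80× of *uniform* coverage and
routinely fail on such spikes, and naive random down-sampling throws away
exactly the rare reads from the starved regions that the assembly needs
most.

`kmernorm` reduces a read set to roughly uniform coverage **without a
reference genome**, for users preparing MDA/SISPA (or simply
over-sequenced) libraries for de novo assembly.

## The method

1. **RMKF.** Count every k-mer (default k = 19) across the whole input,
   forward strand only — forward and reverse-complement k-mers are *not*
   merged. Each read's **R**ead **M**edian **K**-mer **F**requency,

   RMKF(read) = median over the read's N-free k-mers of their dataset counts,

   is a reference-free proxy for the read's true sequencing depth (lower
   median on even-length lists). Reads with RMKF = 0 or fewer than k
   non-ambiguous bases are removed.

2. **Retention bins.** Given a user cutoff *C* and *Z* bins (default 100),
   a read with RMKF ≤ *C* goes to bin *Z* — the 100 % retention bin — and
   is always kept. Otherwise its bin is

   b = ⌈(C / RMKF) · Z⌉, clamped to b ≥ 1,

   so a read 5× more abundant than the cutoff lands in the 20 % bin.
   Because strands are counted separately, *C* corresponds empirically to
   about half the desired output coverage.

3. **Selection.** Each bin's quota is S_b = |bin b| · b / Z (half-up
   rounding). The **random** method shuffles each bin and takes the quota.
   The **targeted** method first clusters each bin's reads
   (cd-hit-est-style greedy clustering at 90 % identity over ≥ 40 % of the
   shorter sequence) and walks clusters smallest — most unique — first,
   recomputing the per-cluster ideal ⌈S_remaining / clusters_remaining⌉
   after every cluster; with `--track-mates` it prefers, in order:
   two-sided pairs within the cluster, mates of already-selected reads,
   mates not yet evaluated, then fragments and orphans whose mate was
   discarded.

## Worked example

Simulate a 20 kb genome sequenced at 200× with a 3× trough in the first
two 1 kb windows (the MDA situation in miniature), then normalize with the
targeted method at an RMKF cutoff of 20:

```sh
kmernorm simulate --out-prefix demo --genome-len 20000 --window-len 1000 \
    --base-depth 200 --spike 0 2 3 --seed 7
# simulated 36060 reads over 20 windows

kmernorm reduce --frag demo.reads.fasta --cutoff 20 --method targeted \
    --seed 7 --out-prefix reduced
# input 36060 reads; removed 0; selected 8953 (0 two-sided pairs)

kmernorm evaluate --truth demo.truth.tsv --profile demo.profile.tsv \
    --ids reduced.selected_ids.txt
# n_reads        8953
# mean_depth     44.765
# max_depth      53.612
# fivefold_fraction      0.9
```

Reading the numbers: 36,060 reads at a mean of 180× became 8,953 reads at
~45× — about 2 × the cutoff of 20, as the strand-separate counting
predicts — and the deepest window fell from 209× to 54×, while every read
of the 3× trough was kept (bin 100 is never down-sampled) so the fraction
of windows at ≥ 5-fold coverage is unchanged. The spike-to-trough contrast
that breaks OLC assemblers is gone; the rare sequence is not.

`reduce` also writes a per-bin report (`.bins.tsv`), a selection report
(`.selection.tsv`), an id sidecar (`.idmap.tsv`), the selected reads split
into `*.paired.*`/`*.fragments.*`, and a JSON run manifest whose stage
counts must reconcile.

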