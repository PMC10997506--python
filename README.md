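# mbrobust

A toolkit for checking the robustness of microbiome signals recovered from
host-dominated sequencing data (tumor tissue, blood, and similar samples
where >99% of reads are host-derived). It packages four pieces of
computational machinery that such studies need but that are usually
scattered across shell one-liners and notebooks:

1. **Exhaustive database cleaning** (`mbrobust.exhaustive`). Host reference
   genomes are tiled into overlapping windows of length *w* = 150 bp at
   stride *s* = 75 bp (windows shorter than 75 bp or containing ≥ 100 N's
   are dropped). Every placement of a window in a microbial reference
   database — from any external aligner via SAM, or from the built-in
   deterministic exact matcher — is converted to a reference interval
   `[pos − 1, pos − 1 + |SEQ|)`, clipped to the contig, sorted,
   deduplicated, merged at distance 0 with a support count (the
   `bedtools merge -c 5 -o count` semantics), and masked to `N`. Because
   the stride is *w*/2, a shared segment of length ≥ *w* aligned to the
   stride grid is masked exactly. An `awk_compat` mode reproduces the
   historical stream pipeline that printed the 1-based SAM position into
   BED context (a +1 shift), so published outputs can be regenerated
   byte-for-byte.

2. **False-positive leakage simulation** (`mbrobust.simulate`). Paired-end
   2×150 bp reads are simulated from a host-only genome (fragment length ~
   round(*N*(270, 27)) clamped, ⌊*c·L*/300⌋ pairs per contig at fold
   coverage *c*, replicate seeds 42, 43, …), optionally subsampled and
   sequentially depleted against host references (a pair survives only if
   *neither* mate matches), and the survivors are mapped against a microbial
   database. Every hit is by construction a false positive; the estimate is
   the leaked fraction of pairs and the number of distinct taxa hit, with
   mean ± sd across replicates.

3. **Conservative taxon filtering** (`mbrobust.filtering`). Step (i):
   intersection with a human-association whitelist (curated catalogs;
   viruses/phages may be exempted since such catalogs omit them). Step
   (ii): read count ≥ 10 AND unique k-mer count ≥ 1000 (boundary
   inclusive), or aggregate genome coverage — the fraction of a genome
   covered by at least one read across a *set* of samples — at ≥ 50%
   (75%/90% as stricter alternates), with a kept species defined by any
   constituent genome passing and a post-hoc manual exclusion list.

4. **Feature-concordance statistics** (`mbrobust.concordance`). For two
   classifiers over a shared feature universe: a 2×2 used/unused
   contingency table tested with Fisher's exact test (one-sided enrichment
   by default); Kendall's τ-b on rankings where used features get ranks
   1..k by descending importance and all unused features are assigned rank
   k+1; Fisher's method (−2 Σ ln p ~ χ²(2m), log-space, underflow clamped
   at the smallest normalized double ≈ 2.2 × 10⁻³⁰⁸) to combine per-batch
   p-values, Benjamini–Hochberg across classes; AUROC/AUPR with
   normal-approximation 99% CIs and an interval-overlap equivalence test.

`mbrobust.fixtures` generates every input with known ground truth (planted
host segments verified substring-disjoint elsewhere, importance pairs with
controlled overlap, taxon tables straddling thresholds), so the whole
toolkit is testable with no downloads.

## Worked example

Generate a 3-genome database with two 300 bp host segments planted at known
positions, clean it, and compare recovered intervals to the truth:

```console
$ mbrobust fixtures make-db --seed 7 --n-segments 2 -o fx
$ mbrobust exhaustive fx/host.fa fx/db.fa -o cleaned
INFO mbrobust: masked 600 bases in 2/3 genomes
$ cat cleaned/intervals.bed
g1      1862    2162    3
g2      2333    2633    3
$ cat fx/truth.bed
g1      1862    2162    1
g2      2333    2633    1
```

Both planted segments are recovered exactly (the support column counts the
three overlapping 150/75 windows that tile each 300 bp segment). The masked
FASTA (`cleaned/masked.fa`) is byte-identical to the input outside these
intervals, and `cleaned/report.tsv` records 300 masked bases in each of the
two affected genomes.

Concordance of two models that share 35 of 40 used features out of 200:

```console
$ mbrobust fixtures make-importances --seed 7 --n-features 200 --k-used 40 \
    --overlap 35 --rank-noise 0.1 -o imp
$ mbrobust concordance imp/model_a.tsv imp/model_b.tsv -o conc.tsv
$ cat conc.tsv
metric  value
used_both       35
used_a_only     5
used_b_only     5
used_neither    155
fisher_p        2.64482e-28
odds_ratio      217
kendall_tau     0.830501
tau_p   3.1499e-38
```

The joint-usage enrichment is overwhelming (p ≈ 3 × 10⁻²⁸) and the
rankings agree strongly (τ-b = 0.83) — the pattern expected when two model
variants learn the same signal.

Every subcommand writes a JSON manifest (parameters, seeds, SHA-256 digests
of inputs and outputs); `mbrobust rerun <manifest>` replays any invocation
byte-for-byte.

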