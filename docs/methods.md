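# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind each module. It states nothing that the test suite
or `scripts/acceptance.py` does not itself compute.

## Window-based database cleaning

**Procedure.** The contaminant reference (one or more host assemblies) is
tiled into windows of length 150 at stride 75, starting at positions 0, 75,
150, … of every contig; the final windows are truncated at the contig end
and kept as long as they are at least 75 bp; windows with ≥ 100 N's are
dropped. Each window is located in the target database, each placement
becomes the reference interval `[POS − 1, POS − 1 + |SEQ|)`, intervals are
clipped to the contig, sorted by (contig, start), exact duplicates removed,
overlapping and book-ended intervals merged at distance 0 with a support
count, and the merged spans replaced by `N`.

**Why stride = length/2 matters.** Every reference position inside a
segment of length ≥ 150 that starts on the stride grid is covered by a
full window lying wholly inside the segment, so grid-aligned shared
segments are masked exactly. Off-grid segments are under-covered by up to
stride − 1 = 74 bases per edge, because a window straddling the segment
boundary is not an exact full-length match. This asymmetry is inherent to
the window design, not to the implementation; the acceptance suite checks
both regimes.

**Coordinate conventions.** Internally and in BED output, coordinates are
0-based half-open; SAM `POS` is converted by −1. The historical stream
implementation piped SAM through an awk program printing `$4` (1-based) and
`$4 + length($10)` straight into BED context, a one-base shift;
`awk_compat=True` reproduces that literal behaviour, and the shifted
intervals equal the standard ones +1 before clipping. Both modes clip
interval ends to the contig length. Interval ends derive from the sequence
field length and ignore CIGAR (insertions, deletions, soft clips), again
matching the stream pipeline; with the built-in exact matcher the two
notions coincide. Secondary alignments (flag 0x100) are *kept* by default —
the stream pipeline did not filter them — with an `exclude_secondary` flag
for the stricter convention. SAM records with `SEQ='*'` are rejected rather
than silently measured as length 1.

**Built-in matcher.** Exact, both strands, all (overlapping) occurrences,
no hit cap, deterministic output ordered by (contig, pos). A real aligner
run with a permissive score floor tolerates a handful of mismatches per
150 bp window and caps reported hits; the matcher is therefore a lower
bound on sensitivity, used for deterministic testing. Externally produced
SAM is the fidelity path.

**Alphabet policy.** Sequences are uppercased on FASTA ingest; any
character outside `{A,C,G,T,N}` is a hard format error naming the contig
and offset. Silent coercion to N would corrupt the masking accounting.

## False-positive leakage simulation

**Model.** Per contig of length L, ⌊c·L/(2·150)⌋ pairs at fold coverage c.
Fragment start uniform on [0, L − 150]; fragment length round(N(270, 27))
clamped to [150, L − start]; mate 1 is the fragment prefix, mate 2 the
reverse complement of the fragment suffix. The only error process is an
optional uniform per-base substitution (default 0). Replicates use seeds
42, 43, … (one increment per sample), for both simulation and subsampling.
These defaults mirror the standard 2×150 HiSeq simulation configuration
(read 150, insert 270 ± 27, 1× coverage, ten replicate samples, one million
pairs subsampled per replicate).

**What is deliberately absent.** Position-dependent quality profiles,
indels, optical duplicates, adapter read-through. Determinism and an
exactly enumerable null are the requirements here; an empirical profile
simulator can replace this stage wherever FASTQ is accepted.

**Depletion contract.** References are applied sequentially; after each, a
pair survives only if neither mate matches. Under an exact matcher this
both-mates rule yields the same survivor set as the published
paired-then-single-end re-pass (a pair is removed iff some mate matches
some reference, in either scheme); under a gapped aligner the two schemes
can differ, which is a documented divergence.

**Counting convention.** The denominator defaults to pairs; `per_read=True`
switches to mates (denominator 2n). Published "percent of reads" figures
are ambiguous between the two, so both are exposed and neither is guessed.
Taxon granularity is whatever the genome→taxon map provides (genus by
convention).

**Exact null and signal.** With host and database verified to share no
75-mer (either strand), no read can map and the leaked fraction is exactly
0 — not merely small. With a planted shared segment, the leak probability
has a closed form by enumerating fragment placements (start × discretized
clamped-normal length); the acceptance suite requires the pooled estimate
over 20 seeds × 50 000 pairs to sit in the binomial 99% CI of that
expectation.

## Taxon filtering

Whitelist labels are normalized (case folded, whitespace collapsed) before
membership tests; dropped taxa are reported with reasons. Read/k-mer
thresholds are conjunctive and boundary-inclusive (10 reads AND 1000 unique
k-mers passes). Threshold aggregation defaults to any-sample (a taxon
passes if any single sample meets both thresholds at once); a summed mode
pools counts first — the published phrasing does not distinguish them, so
both exist. Aggregate coverage is the union of per-sample intervals per
genome divided by genome length; caching per-sample intervals lets
per-subset coverages (e.g. by sample type) be recomputed without
re-reading alignments. A species with several genomes is kept when any one
genome passes (the best-single-genome rule; pooling intervals across a
species' genomes is the alternative and is not what is implemented).
Manual exclusions are configuration, applied after filtering.

## Concordance statistics

**Used/unused.** A feature is used iff its importance is strictly positive.
The 2×2 table (both, A-only, B-only, neither) is tested with Fisher's
exact test, one-sided `greater` by default because the scientific question
is enrichment of joint usage; two-sided is a flag. Degenerate margins give
p = 1 with a warning.

**Ranks.** Used features are ranked 1..k by descending importance with
midranks for score ties; every unused feature receives the fixed rank
k + 1 (k is per-vector). This creates large tie blocks, so the tie-corrected
τ-b with the tie-adjusted normal p-value is the only defensible variant;
τ-a would be distorted by the zero block. Vectors with fewer than two used
features are rejected (degenerate variance).

**Meta-analysis.** Fisher's method is computed in log space
(`chi2.logsf(−2 Σ ln p, 2m)`); a single p-value passes through unchanged;
reported p-values are clamped at the smallest positive normalized double
(`sys.float_info.min` ≈ 2.225 × 10⁻³⁰⁸) with the exact log10 value
available separately, so −log10 displays cap at ≈ 307.65 instead of
overflowing. BH adjustment is the standard step-up, returned in input
order. Classes below the minimum per-class sample size (default 20) are
excluded before comparison.

**Metrics.** AUROC is the rank statistic (ties get half credit); AUPR is
the non-interpolated stepwise sum Σ (R_i − R_{i−1}) P_i by default with a
trapezoidal alternative. Confidence intervals on per-fold/per-batch series
are normal-approximation mean ± z·sd/√n (z = 2.576 at 99%, 1.960 at 95%),
truncated to [0, 1]; equivalence of two series means their intervals
overlap. With fewer than two values the CI collapses to the point with a
warning.

**A caveat the tests surface deliberately.** The exact Fisher test is
discrete: at fixed margins (universe 1240, 100 used per model) the
attainable rejection level nearest to and below 0.05 is
`hypergeom.sf(13; 1240, 100, 100)` = 0.0245, so the observed null rate of
p ≤ 0.05 sits near 0.024, conservative relative to the nominal 0.05. This
is a property of exact conditional tests, not an implementation artifact;
the power ordering (median p strictly decreasing as planted overlap grows)
is the check that does discriminate a broken implementation.

## Synthetic fixtures

Genomes are uniform-random over ACGT — no GC skew, repeats, or real
k-mer spectra — so passing tests demonstrate algorithmic correctness, not
performance on repetitive biological sequence. Planted segments are copied
from host to database at recorded positions with target spans separated by
at least one window length (distinct truth intervals never merge). Two
guarantees are enforced at generation time: segment flanks are resampled
when the adjacent database base equals the adjacent host base (otherwise a
shared substring would extend one base past the recorded truth with
probability 1/4 per boundary), and the finished fixture is verified so that
every database 75-mer not wholly inside a truth interval is absent from the
host on both strands; generation retries on violation and errors out after
a bounded number of attempts. Importance-pair fixtures either fix the
used-set overlap exactly (power/recovery designs, with adjacent-swap rank
noise) or draw model B's used set uniformly and independently (null
design, giving a hypergeometric overlap). Taxon-table fixtures place
probes exactly at, just below, and above each threshold and record the
expected pass sets.

## Problem sizes and numerical choices

Oracle-equivalence sweeps use databases of a few kilobases per genome and
hosts around 1–3 kb (100 seeded fixtures); planted-recovery checks use 20
seeds; the leakage experiment uses a 100 kb host at fold coverage 150
(50 000 pairs per replicate, 20 replicates) against a 10 kb + 10 kb
database; type-I simulations use 500–1000 model pairs. These sizes were
chosen so each property is measured with comfortable statistical margin
while the whole suite runs in a couple of minutes on one core; all scale
linearly if larger instances are wanted. Statistical comparisons against
enumeration oracles use absolute tolerances of 1e-9 to 1e-12; stochastic
comparisons use binomial 99% bands at the stated n.

## Known limitations

* The built-in matcher is exact-only; mismatch-tolerant sensitivity
  requires an external aligner (consumed via SAM).
* Distinguishing biological host-sequence integration (e.g. retroviral)
  from contamination is out of scope; flagged regions are masked either
  way.
* The read simulator's error model is substitution-only and uniform.
* Whitelist catalogs are user-supplied; the toolkit does not curate
  human-association evidence.
* Coverage unions are computed from provided per-sample intervals; the
  toolkit does not parse alignments into coverage itself.
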