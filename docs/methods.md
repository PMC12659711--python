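# Methods

`methdyn` analyses whole-genome bisulfite sequencing (WGBS) of rice panicle
and flag leaf from two cultivars (drought-tolerant N22, drought-sensitive
IR64) under control and field-drought conditions, starting from per-cytosine
counts. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Methylcytosine calling

After bisulfite conversion an unmethylated cytosine reads as T; conversion
occasionally fails, so a truly unmethylated cytosine is observed methylated
at a small non-conversion rate *e*. The rice chloroplast genome is
unmethylated, so each library's *e* is estimated as the pooled
methylated-read fraction over all chloroplast cytosines (all contexts, both
strands). The estimate is floored at 1e-4 so the null stays defined when a
simulated library produces zero errors.

A cytosine with coverage *n* and *k* methylated reads is tested against
X ~ Binomial(*n*, *e*) with the one-sided upper tail p = P(X ≥ k).
One-sided because methylation can only inflate the methylated-read count
above the error rate. Calls require:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 5 reads | minimum coverage for any call |
| `alpha` | 0.005 | per-site p-value cutoff |
| `error_floor` | 1e-4 | lower bound on *e* |

A sample's consensus methylome keeps the sites called in **both** biological
replicates, each replicate tested against its own *e*; no site-level
multiple-testing correction is applied (the raw-p cutoff is itself the
stated rule). The consensus level of a site is the coverage-weighted mean of
the two replicates' k/n, i.e. (k₁+k₂)/(n₁+n₂).

Drought dynamics are classified per site on the control/stress consensus
pair: DI (demethylated; control only), DII (de novo; stress only),
maintained (both). The classes partition the union and are mutually
exclusive by construction.

Cytosine contexts are CpG, CHG and CHH (H ∈ {A,C,T}), read on the
cytosine's own strand: the two bases downstream of a minus-strand cytosine
are the complemented reference bases immediately to its left. A site whose
two downstream bases are not both determinable (contig edge, or an N) is
excluded rather than guessed and counted in the log; the two strands of a
CpG dyad are independent sites.

## Windowed differential methylation

Each contig is tiled into non-overlapping 100-bp windows anchored at the
contig origin; the trailing short window is tested like any other. Each
context is tested separately. For a pair of samples the two replicates'
counts are summed per site, then summed over the window's cytosines — only
cytosines with depth ≥ `min_depth` in **both** samples contribute, and their
number is the window's coverage. The pooled 2×2 table
[[meth_A, unmeth_A], [meth_B, unmeth_B]] gets a two-sided Fisher exact test.
A window is a DMR when jointly:

| filter | default |
|---|---|
| Fisher p | < 0.01 |
| Benjamini–Hochberg q (family = one context × one comparison) | < 0.05 |
| covered cytosines of the window's context | ≥ 5 |
| level fold change FC = max(a,b)/max(min(a,b), ε), ε = 0.01 | > 1.5 |

The ">1.5-fold methylation level variance" rule is read as a ratio of pooled
window levels with pseudocount ε — the standard reading for windowed
Fisher-based DMR callers. Direction is *hyper* when the focal sample's level
is higher; the focal samples are panicle (tissue-DMRs), N22 (cultivar-DMRs)
and drought (drought-DMRs). Swapping the samples preserves the DMR set and
flips every direction (the test is symmetric and the FC is too); ties in
level cannot pass the FC filter, so no tie-break is needed. Replicate-aware
tests (beta-binomial, logistic) and merging of adjacent significant windows
are deliberately out of scope: counts are reported per window.

The same filter stack applied to miRNA-locus features — mature, precursor,
three 1-kb promoter bins upstream of the precursor start and three 1-kb
downstream bins past its end, strand-aware, truncated at contig bounds —
yields differentially methylated features (DMFs), with the BH family per
context across all features. Mature features (~21 bp) rarely hold five
covered cytosines and are then excluded by the coverage filter; this is
visible in the output rather than silently dropped.

### Fisher implementation

The per-window test is computed vectorised: log-pmfs of the hypergeometric
support from a cached log-factorial table, two-sided p as the sum of
pmf(k) ≤ pmf(observed)·(1+1e-7) — the standard tie tolerance. This path is
checked in the tests against both `scipy.stats.fisher_exact` and an
independent `scipy.stats.hypergeom` enumeration (agreement to better than
1e-10 relative error on random tables with margins up to 200).

## Annotation and profiles

Every genomic position maps to exactly one feature by precedence, mirroring
promoter-first peak-annotation conventions:

promoter(≤1 kb) > 5′UTR > 3′UTR > exon > intron > promoter(1–2 kb) >
promoter(2–3 kb) > downstream(≤1, 1–2, 2–3 kb) > distal intergenic;
among equal-precedence overlaps the nearest TSS wins. The exact priority
order is a package choice (the feature shares depend on it) and the
promoter/downstream extent (3 kb in 1-kb bins) is configurable. Regions are
labeled by their midpoint — windows are only 100 bp, so full-overlap
weighting would not change the tallies materially.

Metagene profiles use 30 × 100-bp upstream bins, the gene body rescaled to
40 bins TSS→TES, and 30 × 100-bp downstream bins, strand-flipped for
minus-strand genes; bins without covered cytosines are missing, not zero.
DI/DII positional-abundance curves count sites per bin, normalised per kb
per gene within each expression class (flank bins 0.1 kb; body bins
gene-length/40).

## Expression integration

Genes are classed on mean FPKM under stress: silent (< 0.5), then
low/medium/high by linear-interpolation quartiles of the remaining genes'
stress FPKM (≤ Q2, ≤ Q3, else high); silent genes are excluded before
quartiling because "silent" is defined first. Differential expression is
consumed as an upstream table; a DEG needs FPKM ≥ 0.5 in the larger
condition, FDR ≤ 0.05 and a two-fold change. A DMR–gene link is *negatively
correlated* when directions oppose (hyper & down, or hypo & up) — the
categorical reading; a quantitative correlation of levels is not computed.
Genes linked to both hyper and hypo DMRs count in both tallies and are
flagged `mixed`. The same categorical rule extends to miRNAs (feature hyper
+ miRNA down ⇒ anti-correlated) and their degradome-predicted targets
(miRNA down + target up ⇒ target anti-correlation); target lists arrive
pre-filtered.

## Association statistics

Direction-by-context (and similar) tallies are tested with Pearson χ²
without continuity correction; effect size is Cramér's V =
√(χ²/(n·min(r−1,c−1))), uncorrected — the published values match the
uncorrected formula, so no small-sample bias correction (Bergsma) is
applied. The 95% CI is a percentile bootstrap over multinomial resamples of
the table at fixed grand total (B = 2000 by default, seeded); resamples with
a zero margin are redrawn. The percentile bootstrap of V is upward-biased at
small n; its coverage is checked at grand totals in the thousands,
comparable to the DMR tallies it is used on. The verbal labels
(negligible/weak/moderate/strong at 0.1/0.3/0.5, closed on the left) are
descriptive only, never filters.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, from
one integer seed, at a scale where the whole pipeline runs in about a minute
on one CPU (default: two 200-kb nuclear chromosomes + a 20-kb chloroplast,
~2·10⁵ cytosine sites, 120 genes, 20 miRNA loci, 2 cultivars × 2 tissues ×
2 conditions × 2 replicates):

- **Baseline levels** per context from Beta distributions (CpG Beta(5,2),
  CHG Beta(2,3), CHH Beta(1,12)), drawn per 100-bp block and shared by the
  block's sites. Methylation is locally correlated in real genomes; the
  block-level draw reflects that, and it also keeps the pooled window test
  calibrated — with i.i.d. per-site levels, random depth weighting inflates
  between-sample window-level differences beyond hypergeometric expectation
  and the Fisher test becomes anticonservative.
- **Counts**: depth per cytosine i.i.d. negative binomial (mean 20,
  dispersion 5); methylated reads Binomial(depth, m + (1−m)·e) with
  e = 0.014; the chloroplast's true level is identically zero.
- **Planted DMRs** on three axes (tissue, cultivar, drought-per-cultivar;
  20 each by default): 100-bp windows whose midpoint lies in a gene body,
  clear of any neighbouring gene's ≤1-kb promoter (whose precedence would
  re-assign the annotation), holding ≥ 6 cytosines of the target context;
  the target-context sites take 0.15 on the reference side and 0.55 on the
  focal side, clearing the 1.5-fold filter by construction. Drought plants
  are cultivar-specific, so they legitimately also surface in the
  stress-condition cultivar comparison — mirroring the drought-specific
  cultivar differences the real study reports.
- **Expression**: a configured fraction (default 1.0) of drought-DMR host
  genes move oppositely (hyper → down, hypo → up) with FDR and fold-change
  set to pass DEG selection exactly; background DEGs and silent genes are
  sprinkled in. miRNA feature plants repress the miRNA and their targets'
  expression comes from the same tables.

Not emulated: read-level simulation, sequencing error beyond conversion
failure, positional autocorrelation beyond 100-bp blocks, transposon
architecture, and realistic genome-scale DMR counts. Passing recovery tests
therefore demonstrates the correctness and calibration of the machinery
under the stated statistical structure, not performance on real WGBS
texture.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; 1-based on-disk formats (CX
  reports, GFF3) convert at the boundary; BED is written 0-based.
- All-zero Fisher tables give p = 1 with a warning; empty CX files give an
  empty table with a warning.
- Kernel density of methylation differences: Gaussian KDE with Silverman
  bandwidth on a fixed 512-point grid over [−1, 1]; degenerate (zero
  variance) differences fall back to a fixed bandwidth of 0.01.
- Degenerate expression quartiles (all non-silent FPKM equal) put every
  non-silent gene in `low` with a warning.
- Truncated promoter/downstream bins at contig bounds keep their names with
  reduced extent; empty truncated miRNA features are flagged, not dropped.
- Determinism: every stochastic step takes a seed or a spawned child of the
  run seed; identical seeds give byte-identical output files, verified by
  SHA-256 in the run manifest.

## Problem sizes used in the checks

The acceptance checks run the conversion-error recovery at 5,000
chloroplast cytosines × 100 replicate simulations; the type-I check at 10⁵
unmethylated sites at depth 20; the DMR null at 10 × 10,000 windows and the
planted check at 100 planted windows of 8 cytosines at depth 20 among
10,000; and the end-to-end determinism/recovery check on a reduced study
(two 50-kb chromosomes, 30 genes, 6 miRNA loci, 5 planted DMRs per axis).
These sizes are the package's own defaults for its test conditions; the
generator scales above them with configuration only.

## Known limitations

- Pooling replicates before the Fisher test discards between-replicate
  variance; a replicate-aware test would be more conservative on real data.
- Per-context error rates are logged but not used (one pooled *e* per
  library).
- The bootstrap CI for Cramér's V under-covers at small grand totals
  (percentile method bias); the labels and CIs are descriptive.
- The feature-precedence order is a convention; shares shift if it changes.
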