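# Methods

## Coverage model for CNV inference

Off-target scATAC fragments (those not overlapping any called peak)
are treated as a near-uniform sample of accessible genomic DNA whose
local density is proportional to copy number, modulated by a smooth
GC-dependent amplification efficiency.  The inference chain is:

1. **Windows.** Each chromosome is tiled with fixed-size windows
   (default 2 Mb for per-cell work, 1 Mb for pooled cluster-level
   profiles, where depth permits the finer grid).  A terminal
   remainder ≥ half the target size becomes its own window, otherwise
   it is merged into the previous window, so windows always partition
   the chromosome.
2. **Effective length.** Peak base pairs are subtracted from each
   window (`effective_length = window − peak bp`), because peak
   territory is excluded from off-target counting; dividing counts by
   the effective length compensates windows dense in peaks.  Windows
   with no effective length, or without a defined GC fraction, are
   flagged unusable and propagate as missing values.
3. **Counting.** A fragment is assigned to the window containing its
   midpoint (unambiguous for boundary-spanning fragments) and weighted
   by its duplicate count (a flag collapses duplicates to 1).
   Fragments overlapping a merged peak by ≥ 1 bp are off-target-
   excluded — the strictest reading of "off-target".
4. **Normalization.** Per-bp rates are divided by the entity's mean
   rate over usable autosomal windows, making profiles invariant to
   sequencing depth.  Sex chromosomes are excluded from the baseline
   (and from clustering) by default because their ploidy is ambiguous.
5. **GC-matched background.** For each usable window the `n_match=100`
   other usable windows closest in GC fraction are selected (ties
   broken by genomic order; if fewer candidates exist, all are used).
   The log2 fold change of a window's coverage over the mean coverage
   of its matched set cancels any bias that is a smooth function of
   GC, because matched windows share the query's efficiency.  The
   background is computed within the same entity's own profile, so a
   CNV-free cell population shows a flat profile with no external
   reference.  Matching is genome-wide, not per-chromosome: windows of
   similar GC on other chromosomes are equally valid efficiency
   controls, and the larger candidate pool tightens the match.
6. **Pseudocount.** `ε = 0.01` on normalized coverage bounds the
   log2FC of an empty window at ≈ −6.6 instead of −∞; a planted
   homozygous deletion therefore reads as a strongly negative (≤ −2)
   but finite segment.

The matching step only works when the candidate pool is large: with
100-window backgrounds drawn from only a few hundred windows, the
matched sets of GC-extreme windows are one-sided and a monotone
residual trend survives.  The residual becomes negligible from
roughly 1,500 windows — i.e. genome-scale input at megabase windows —
which is the regime the method is designed for (and the scale the
synthetic genome reproduces).

## Segmentation

Profiles are segmented per chromosome by exact penalized least-squares
changepoint fitting (optimal partitioning by dynamic programming):
minimize total within-segment squared error plus β per changepoint.
The noise scale is estimated robustly from the data as
σ̂ = median(|Δx|)/(0.6745·√2) — successive differences are insensitive
to the segment structure itself — and the default penalty is
β = 4·σ̂²·ln n.  This calibration (chosen by simulation) keeps flat
noisy profiles unsegmented (false-split rate ≤ ~5% at 50 windows,
< 1% at realistic lengths) while localizing a 10-window event of
amplitude log2(3/2) at noise SD 0.15 to within one window in > 99% of
runs.  Greedy binary segmentation was rejected: its first split over a
centered event is marginal against any safe penalty, and it misses
such events in ~25% of runs.  A simple per-changepoint constant
penalty (without the ln n factor) over-segments flat profiles at these
lengths.  Alternative algorithms can be plugged in behind
`segment_profile(values, penalty)`.

## Clone clustering and concordance

Per-cell log2FC vectors (2 Mb bins, missing imputed to 0, autosomes
only) are clustered with K-means (fixed seed, best of 25 restarts by
within-cluster sum of squares).  Cluster labels are made deterministic
by relabeling in increasing mean |log2FC|, so label 0 is always the
flattest, normal-like population.  Epigenetic labels come from marker
promoters (TSS ± 2 kb by convention; the window is configurable):
SOX2 accessibility gates tumor vs normal (≥ 1 fragment — per-cell
promoter signals are near-binary), then ASCL1 vs NEUROD1 promoter
accessibility types tumor cells, with both-or-neither cells labelled
ambiguous.  Concordance between the two partitions is reported as a
contingency table, adjusted Rand index, and per-genetic-cluster
majority purity; ambiguous cells are excluded but counted.  A genetic
clone whose cells carry both subtypes then shows up not as a fourth
epigenetic state but as a cluster whose purity equals the mixing
proportion.

## Quality control

scATAC cells are scored by total fragments and FrIP (count-weighted
fraction of fragments overlapping merged peaks, ≥ 1 bp overlap —
whole-fragment, not midpoint, matching the standard FrIP definition).
Cells with FrIP < 0.2 or fewer than 1000 fragments are removed;
boundary values are retained (removal is strict inequality).  snRNA
cells are kept with ≥ 200 expressed genes and ≤ 80% mitochondrial
UMIs (prefix `MT-`, configurable), boundaries again retained.

## Subtype signatures

The two-group differential test is an internal simplified procedure:
library-size normalization to the mean depth, log2(x+1), per-feature
Welch t-test, Benjamini–Hochberg adjustment.  Region thresholds follow
the analysis conventions (NE-vs-AD: adjusted p < 0.001 and
log2FC > 2; subtype: adjusted p < 0.01 and |log2FC| > 1 split by
sign).  Peak summits link to the nearest TSS within ±50 kb (distance
ties go to the lexicographically smaller gene id).  Signature genes
are the top 50 linked, up-regulated genes by `log2FC × (−log10 p)` —
raw p, since the construction score is a ranking device, not an
inference; the log base only rescales scores and cannot change the
ranking.  Scoring uses the plain signed single-sample KS rank
statistic rather than a kernel-smoothed CDF variant: genes are ranked
by expression (descending, stable order for ties), hits add 1/|S| and
misses subtract 1/(N−|S|), and the score is the running sum's
extremal deviation.  The statistic is invariant to any strictly
monotone transform of a sample's expression.  The TF ratio uses a
pseudocount of 1 on both genes (samples with zero NEUROD1 expression
exist in practice) before cohort z-scoring; association between ΔKS
and the z-ratio is Spearman's rho with average ranks and the
t-approximation p-value.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed and defines the conditions all
property checks run under.

* **Genome**: five 300 Mb chromosomes (1.5 Gb — 750 windows at 2 Mb,
  1,500 at 1 Mb), enough windows for 100-window GC backgrounds to be
  two-sided, as on a real genome.  GC is smoothed white noise per
  chromosome (moving average over 7 Mb), mean 0.5, SD 0.12, clipped to
  [0.30, 0.70], generated once at 1 Mb resolution so any window tiling
  sees a consistent landscape.
* **GC bias**: multiplicative efficiency 1 + 0.6·(GC − 0.5) — a
  ±12% amplification-efficiency swing across the GC range; slope 0
  turns the bias off so tests can isolate the correction.
* **Population**: 600 cells in three equal clones — normal; an
  ASCL1-subtype clone with a 20 Mb 4-copy gain; a NEUROD1-subtype
  clone with a 10 Mb single-copy loss.  Clones may also mix subtypes
  with stated probabilities (used for the mixed-clone scenario).
* **Fragments**: 16,000 per cell (10x-scale deep scATAC), FrIP
  Beta-distributed around 0.30 (SD 0.04).  In-peak fragments choose a
  peak (2,000 background peaks plus marker promoters; marker weight
  ×10, gated by tumor status and subtype); off-target fragments are
  Poisson per (cell, 1 Mb bin) with intensity ∝ copy number × GC
  efficiency × bin length, then uniform positions — exactly the
  coverage model the CNV method assumes, which is what makes
  parameter-recovery tests interpretable.
* **Expression**: two 50-gene programs (markers ASCL1 / NEUROD1
  included), log2 effect 2 between pure subtypes, per-gene baseline
  offsets, lognormal noise SD 0.5 (log2 units), per-sample mixing
  weights for intermediate phenotypes.

Not emulated: Tn5 sequence insertion bias, doublets, batch effects,
mappability gaps, real peak-density structure, or subclonal CNV
fractions below the clone level.  Passing tests therefore demonstrate
correctness of the inference chain under its own model assumptions and
realistic sparsity/bias levels — not robustness to every artifact of
real libraries.

Determinism: all randomness flows through one seeded numpy PCG64
generator; the GC track can be regenerated independently of the
fragments because it is drawn first from a fresh generator with the
same seed.

## Problem sizes used by the test and acceptance runs

Full-pipeline checks run the default 600-cell, 1.5 Gb configuration
(~10 M fragments, about a minute per run); unit tests use 2 × 60 Mb
genomes with tens of cells.  The segmentation-recovery study uses 50
replicate profiles of 100 windows; the background-matching oracle 500
random window sets; the signature null/power study 20 replicate
cohorts of 20 samples per arm.  These sizes make all checks
statistically decisive while keeping a full run on one CPU within a
few minutes.

## Known limitations

* The fold-change statistic is a ratio of normalized per-bp rates; at
  very low per-window counts its expectation is biased low (Jensen
  gap), which matters for per-cell profiles below ~5 fragments per
  window but not for pooled profiles.
* The K-means step assumes clone-distinguishing events span several
  windows; a sub-window (< 2 Mb) event cannot separate clones here.
* Promoter-based typing needs markers with near-binary per-cell
  signal; low-coverage cells fall into the ambiguous class rather
  than being force-assigned.
* The differential test is a Welch t on transformed counts — adequate
  for ranking and thresholding in the signature pipeline, but not a
  replacement for a negative-binomial count model when per-feature
  inference is the goal.
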