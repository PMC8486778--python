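# clonescope

Single-cell chromatin accessibility (scATAC-seq) of tumors carries two
signals at once: regulatory signal inside called peaks, and a
genome-wide background of *off-target* fragments whose density tracks
DNA copy number rather than chromatin state.  `clonescope` exploits
both to dissect intratumoral heterogeneity in neuroendocrine prostate
cancer (NEPC) and related small-cell carcinomas, where ASCL1- and
NEUROD1-driven subtypes can coexist as distinct genetic clones inside
one tumor:

* **CNV inference from off-target reads.**  The genome is tiled into
  1–2 Mb windows; off-target fragment counts are converted to per-bp
  rates over each window's *effective length* (window minus peak bp)
  and normalized to mean 1 per cell.  Each window is compared to the
  average of its 100 most GC-similar windows — the GC-matched
  background — giving log2 fold changes in which
  amplification-efficiency bias cancels:
  `log2FC(w) = log2((cov(w)+ε) / (mean cov of GC-matched windows + ε))`.
  A diploid window sits at 0, a single-copy loss near −1, a 4-copy
  gain near +1.
* **Segmentation and clone clustering.**  Profiles are segmented by
  exact penalized least-squares changepoint fitting (penalty
  4·σ̂²·ln n, σ̂ from the median absolute successive difference), and
  cells are clustered on their 2 Mb log2FC vectors with K-means to
  recover genetic clones; profile similarity is summarized by pairwise
  Pearson correlation.
* **Cell typing from promoter accessibility.**  Cells are gated
  tumor/normal on SOX2 promoter fragments and typed ASCL1 vs NEUROD1
  by which TF promoter is accessible — the epigenetic counterpart to
  the genetic clusters, compared via contingency tables, adjusted Rand
  index, and per-cluster purity.
* **Subtype signature scoring.**  From differential results, the top
  50 genes by `log2FC × (−log10 p)` with a peak within ±50 kb of
  their TSS form each subtype's signature.  Samples are scored with a
  signed single-sample Kolmogorov–Smirnov rank statistic (hits gain
  1/|S|, misses lose 1/(N−|S|); the score is the extremal running-sum
  deviation, in [−1, 1]).  The score difference
  ΔKS = KS(ASCL1) − KS(NEUROD1) is compared (Spearman) with the
  z-scored ASCL1/NEUROD1 expression ratio.

A fully specified synthetic-data generator (`clonescope.synthetic_data`)
plants multi-clone populations with known CNVs, GC-dependent coverage
bias, per-cell FrIP variation, subtype-linked promoter accessibility
and two anti-correlated TF expression programs, so every stage is
testable against ground truth without any sequencing data.

## Worked example

```python
from clonescope import SimulationConfig
from clonescope.pipeline import run_clone_analysis
from sklearn.metrics import adjusted_rand_score

run = run_clone_analysis(SimulationConfig(seed=1), kmeans_seed=7)
truth = run.truth_cells.set_index("barcode").loc[run.log2fc.index, "clone_id"]
print(adjusted_rand_score(truth, run.genetic_labels))
print(run.clone_segments[run.clone_segments.mean_log2fc.abs() > 0.3])
```

prints

```
0.9602568...
entity chrom     start       end  n_windows  mean_log2fc
cloneA  chr2  40000000  60000000         20     0.953658
cloneB  chr3 100000000 110000000         10    -0.972697
```

i.e. K-means on the per-cell CNV profiles recovers the three planted
populations at ARI 0.96, and segmentation localizes the planted 20 Mb
4-copy gain (expected log2FC = log2(4/2) = 1) and 10 Mb single-copy
loss (expected −1) to the window, with segment means within 0.05 of
the planted values.

The same pipeline is presented as a narrative under `analysis/`
(01 simulate → 02 QC → 03 CNV & clones → 04 signatures →
05 clone–subtype concordance), each step writing its tables under
`results/`.  A thin CLI mirrors the library
(`clonescope simulate|qc|cnv|segment|clones|subtype|concordance|signature`).

## Layout

```
src/clonescope/      genomic_io, synthetic_data, cell_qc, cnv_inference,
                     subtype_signature, clone_concordance, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               unit + property + acceptance suites
docs/methods.md      model, assumptions, parameter choices, limitations
```
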