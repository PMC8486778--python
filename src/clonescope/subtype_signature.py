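"""ASCL1/NEUROD1 subtype signatures and single-sample enrichment scoring.

Signatures are built from differential results: regions pass
significance/fold-change thresholds, peak summits are linked to the
nearest transcription start site within +/-50 kb, and the top 50 genes
ranked by ``log2FC x (-log10 p)`` form each subtype's signature.
Samples are then scored with a signed single-sample Kolmogorov-Smirnov
rank statistic (the enrichment kernel behind GSVA-style scoring): genes
are ranked by expression and the maximum deviation of a hit/miss
running sum measures how concentrated the signature is at the top
(score -> +1) or bottom (-> -1) of the ranking.  The difference
``score(ASCL1) - score(NEUROD1)`` is compared (Spearman) with a
z-scored ASCL1/NEUROD1 expression ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureSet",
    "differential_test",
    "apply_region_thresholds",
    "link_peaks_to_genes",
    "build_signature",
    "ks_enrichment",
    "subtype_delta",
    "normalized_tf_ratio",
    "rank_association",
]


@dataclass
class SignatureSet:
    """A named, ordered gene signature with construction scores."""

    name: str
    genes: list[str]
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def to_json(self, path: str | Path, **provenance) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "genes": self.genes, "scores": self.scores,
                 "provenance": provenance},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"], d["genes"], d.get("scores", []))


def differential_test(counts: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """Two-group differential test on a features-by-samples count matrix.

    Counts are library-size normalized (each column scaled to the mean
    depth), log2(x+1)-transformed; per feature the log2 fold change of
    group means and a Welch t-test p-value are reported, with
    Benjamini-Hochberg adjustment across features.  The fold change is
    group1 - group2 in the sorted order of the two labels.  Features
    with zero variance in both groups get p = 1.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    n1, n2 = (labels == groups[0]).sum(), (labels == groups[1]).sum()
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 samples per group")
    depth = counts.sum(axis=0).to_numpy().astype(float)
    norm = counts.to_numpy() / depth[None, :] * depth.mean()
    logx = np.log2(norm + 1.0)
    a = logx[:, labels == groups[0]]
    b = logx[:, labels == groups[1]]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[zero_var] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature": counts.index,
            "log2_fold_change": log2fc,
            "p_value": p,
            "adjusted_p": np.clip(padj, p, 1.0),
        }
    ).set_index("feature")


def apply_region_thresholds(results: pd.DataFrame, mode: str):
    """Select differential regions at the analysis' stated thresholds.

    ``"ne_vs_ad"``: adjusted p < 0.001 and log2FC > 2 (one set).
    ``"subtype"``: adjusted p < 0.01 and |log2FC| > 1, split by fold-change
    sign into the up set (positive; first group) and down set (negative).
    """
    padj = results["adjusted_p"]
    lfc = results["log2_fold_change"]
    if mode == "ne_vs_ad":
        return list(results.index[(padj < 0.001) & (lfc > 2)])
    if mode == "subtype":
        sig = (padj < 0.01) & (lfc.abs() > 1)
        return (
            list(results.index[sig & (lfc > 0)]),
            list(results.index[sig & (lfc < 0)]),
        )
    raise ValueError(f"unknown mode {mode!r}")


def link_peaks_to_genes(
    summits: pd.DataFrame, tss: pd.DataFrame, max_dist: int = 50_000
) -> dict[str, str]:
    """Map peak summits to the nearest TSS within +/- ``max_dist`` bp.

    ``summits``: columns (peak, chrom, pos); ``tss``: columns
    (gene, chrom, pos) with strand-aware TSS positions and unique gene
    ids.  Distance ties go to the lexicographically smaller gene id.
    """
    if tss["gene"].duplicated().any():
        raise ValueError("TSS table has duplicate gene ids")
    out: dict[str, str] = {}
    for chrom, tgrp in tss.groupby("chrom"):
        tgrp = tgrp.sort_values(["pos", "gene"])
        pos = tgrp["pos"].to_numpy()
        genes = tgrp["gene"].to_numpy()
        sgrp = summits[summits["chrom"] == chrom]
        for peak, p in zip(sgrp["peak"], sgrp["pos"]):
            d = np.abs(pos - p)
            best = d.min()
            if best > max_dist:
                continue
            cand = genes[d == best]
            out[peak] = min(cand)
    return out


def build_signature(
    gene_results: pd.DataFrame,
    linked_genes: Sequence[str],
    n: int = 50,
    name: str = "signature",
) -> SignatureSet:
    """Top-``n`` up-regulated linked genes by ``log2FC x (-log10 p)``.

    Only genes with a linking peak and positive fold change (up in the
    subtype) are eligible; ties are broken by gene id for determinism.
    """
    eligible = gene_results.loc[gene_results.index.isin(set(linked_genes))]
    eligible = eligible[eligible["log2_fold_change"] > 0]
    score = eligible["log2_fold_change"] * (-np.log10(eligible["p_value"]))
    ranked = score.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} eligible genes for a {n}-gene signature")
    top = ranked.head(n)
    return SignatureSet(name, list(top.index), [float(s) for s in top.to_numpy()])


def ks_enrichment(expression: pd.DataFrame, signature: SignatureSet) -> pd.Series:
    """Signed single-sample KS enrichment score per sample, in [-1, 1].

    Per sample, genes are ordered by decreasing expression (ties keep
    matrix order, i.e. behave as average ranks for the deviation's
    extremum); walking down the ranking the running sum gains
    ``1/|S|`` at signature genes and loses ``1/(N-|S|)`` elsewhere.
    The score is the deviation of largest magnitude, keeping its sign:
    +1 when the signature occupies the very top of the ranking, -1 at
    the very bottom.
    """
    present = [g for g in signature.genes if g in expression.index]
    dropped = len(signature.genes) - len(present)
    if dropped:
        warnings.warn(f"{dropped} signature genes absent from the matrix")
    if not present:
        warnings.warn(f"signature {signature.name!r} has no genes in the matrix")
        return pd.Series(np.nan, index=expression.columns, name=signature.name)
    hit = np.asarray(expression.index.isin(set(present)))
    n_genes = len(expression.index)
    n_hit = hit.sum()
    if n_hit == n_genes:
        raise ValueError("signature covers the whole matrix; score undefined")
    X = expression.to_numpy()
    scores = np.empty(X.shape[1])
    inc = 1.0 / n_hit
    dec = 1.0 / (n_genes - n_hit)
    for j in range(X.shape[1]):
        order = np.argsort(-X[:, j], kind="stable")
        steps = np.where(hit[order], inc, -dec)
        running = np.cumsum(steps)
        i = int(np.argmax(np.abs(running)))
        scores[j] = running[i]
    return pd.Series(scores, index=expression.columns, name=signature.name)


def subtype_delta(score_a: pd.Series, score_b: pd.Series) -> pd.Series:
    """score(ASCL1) - score(NEUROD1) per sample; missing propagates."""
    return (score_a - score_b).rename("delta")


def normalized_tf_ratio(
    expression: pd.DataFrame,
    gene_a: str = "ASCL1",
    gene_b: str = "NEUROD1",
    pseudocount: float = 1.0,
) -> pd.Series:
    """z-scored (A + c)/(B + c) expression ratio across the cohort."""
    for g in (gene_a, gene_b):
        if g not in expression.index:
            raise KeyError(f"gene {g!r} not in the matrix")
    ratio = (expression.loc[gene_a] + pseudocount) / (expression.loc[gene_b] + pseudocount)
    if len(ratio) < 2:
        raise ValueError("z-score undefined for fewer than 2 samples")
    sd = ratio.std(ddof=1)
    if sd == 0:
        warnings.warn("constant TF ratio across samples; all z set to 0")
        return pd.Series(0.0, index=ratio.index, name="tf_ratio_z")
    return ((ratio - ratio.mean()) / sd).rename("tf_ratio_z")


def rank_association(delta: pd.Series, z: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    Pairs with a missing value on either side are dropped; at least 3
    complete pairs are required.  Returns (rho, p); rho is NaN for a
    constant vector.
    """
    joined = pd.concat([delta, z], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 paired non-missing values")
    rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)
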