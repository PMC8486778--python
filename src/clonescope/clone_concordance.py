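"""Promoter-based cell typing and genetic/epigenetic concordance.

Tumor cells are gated on accessibility at the SOX2 promoter; tumor
cells are then typed ASCL1 or NEUROD1 by which TF promoter is
accessible (cells with both or neither are "ambiguous").  An
alternative caller scores cells on the top differential regions
between the two subtypes.  Concordance between these epigenetic labels
and the CNV-derived genetic clusters is quantified by a contingency
table, the adjusted Rand index, and per-cluster majority purity —
which resolves whether a genetic cluster is one subtype or an
intermixed population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genomic_io import Region
from .cnv_inference import _peak_overlap_mask

from typing import Mapping, Sequence

__all__ = [
    "promoter_counts",
    "call_cell_labels",
    "signature_accessibility_score",
    "concordance",
]


def promoter_counts(
    fragments: pd.DataFrame,
    promoters: Mapping[str, Region],
    cells: Sequence[str] | None = None,
    genome_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Count-weighted fragment overlaps per cell per marker promoter.

    ``promoters`` maps marker name -> promoter Region (typically TSS
    +/- 2 kb).  ``cells`` restricts and orders the output rows (cells
    with no fragments get zero counts).
    """
    if genome_lengths is not None:
        for name, r in promoters.items():
            if r.chrom not in genome_lengths or r.end > genome_lengths[r.chrom]:
                raise ValueError(f"promoter {name} outside the genome")
    if cells is None:
        cells = sorted(pd.unique(fragments["barcode"]))
    out = pd.DataFrame(0.0, index=list(cells), columns=list(promoters))
    chrom = fragments["chrom"].to_numpy()
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    w = fragments["count"].to_numpy().astype(float)
    barcodes = fragments["barcode"].to_numpy()
    cellset = set(cells)
    for name, region in promoters.items():
        hit = _peak_overlap_mask(chrom, start, end, [region])
        if not hit.any():
            continue
        counts = (
            pd.Series(w[hit]).groupby(pd.Series(barcodes[hit])).sum()
        )
        for b, c in counts.items():
            if b in cellset:
                out.loc[b, name] = c
    out.index.name = "barcode"
    return out


def call_cell_labels(
    acc: pd.DataFrame,
    tumor_marker: str = "SOX2",
    marker_a: str = "ASCL1",
    marker_b: str = "NEUROD1",
    t_tumor: float = 1.0,
) -> pd.Series:
    """Per-cell label from marker-promoter accessibility.

    Cells below the tumor gate (``tumor_marker`` count < ``t_tumor``)
    are "normal" regardless of TF promoters.  Among tumor cells the
    label is the TF whose promoter alone is accessible; cells with both
    or neither accessible are "ambiguous".
    """
    tumor = acc[tumor_marker].to_numpy() >= t_tumor
    a = acc[marker_a].to_numpy() > 0
    b = acc[marker_b].to_numpy() > 0
    labels = np.where(
        ~tumor,
        "normal",
        np.where(a & ~b, marker_a, np.where(b & ~a, marker_b, "ambiguous")),
    )
    return pd.Series(labels, index=acc.index, name="epigenetic_label")


def signature_accessibility_score(
    fragments: pd.DataFrame,
    region_sets: Mapping[str, Sequence[Region]],
    cells: Sequence[str] | None = None,
    margin: float = 1.5,
) -> pd.DataFrame:
    """Score cells on subtype-differential region sets and label by margin.

    Per cell, fragment counts over each subtype's region set are divided
    by the cell's total fragments (depth normalization).  The cell is
    labelled with the higher-scoring subtype when the score ratio
    exceeds ``margin``, else "ambiguous".
    """
    for name, regions in region_sets.items():
        if len(regions) == 0:
            raise ValueError(f"empty region set {name!r}")
    if cells is None:
        cells = sorted(pd.unique(fragments["barcode"]))
    totals = fragments.groupby("barcode")["count"].sum()
    out = pd.DataFrame(0.0, index=list(cells), columns=list(region_sets))
    chrom = fragments["chrom"].to_numpy()
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    w = fragments["count"].to_numpy().astype(float)
    barcodes = fragments["barcode"].to_numpy()
    for name, regions in region_sets.items():
        hit = _peak_overlap_mask(chrom, start, end, list(regions))
        counts = pd.Series(w[hit]).groupby(pd.Series(barcodes[hit])).sum()
        for b, c in counts.items():
            if b in out.index:
                out.loc[b, name] = c / totals.get(b, np.nan)
    names = list(region_sets)
    if len(names) != 2:
        raise ValueError("expected exactly two subtype region sets")
    s1, s2 = out[names[0]].to_numpy(), out[names[1]].to_numpy()
    label = np.full(len(out), "ambiguous", dtype=object)
    label[s1 > margin * s2] = names[0]
    label[s2 > margin * s1] = names[1]
    out["label"] = label
    out.index.name = "barcode"
    return out


def concordance(
    epigenetic: pd.Series, genetic: pd.Series, ambiguous_label: str = "ambiguous"
) -> dict:
    """Agreement between epigenetic subtype calls and genetic clusters.

    Ambiguous cells are excluded (their number reported).  Returns a
    dict with the contingency table (genetic x epigenetic), the
    adjusted Rand index, per-genetic-cluster majority purity, and
    ``n_ambiguous``.
    """
    shared = epigenetic.index.intersection(genetic.index)
    if len(shared) == 0:
        raise ValueError("label sets cover disjoint cells")
    epi = epigenetic.loc[shared]
    gen = genetic.loc[shared]
    keep = epi != ambiguous_label
    n_ambiguous = int((~keep).sum())
    epi, gen = epi[keep], gen[keep]
    table = pd.crosstab(gen, epi)
    ari = float(adjusted_rand_score(gen.to_numpy(), epi.astype(str).to_numpy()))
    purity = {
        str(cluster): float(row.max() / row.sum()) for cluster, row in table.iterrows()
    }
    return {
        "table": table,
        "ari": ari,
        "purity": purity,
        "n_ambiguous": n_ambiguous,
        "n_used": int(len(epi)),
    }
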