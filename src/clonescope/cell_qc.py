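"""Per-cell quality metrics and inclusion filters.

scATAC cells are scored by total fragment count and FrIP (fraction of
fragments in peaks, count-weighted, any-bp overlap); cells with
FrIP < 0.2 or fewer than 1000 fragments are removed (boundary values
kept).  snRNA cells are filtered on the number of expressed genes
(>= 200 with any UMI) and the mitochondrial UMI fraction (<= 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import Region
from .cnv_inference import _peak_overlap_mask

__all__ = ["CellQC", "compute_atac_qc", "filter_atac_cells", "filter_rna_cells"]


@dataclass(frozen=True)
class CellQC:
    barcode: str
    total_fragments: int
    frip: float  # NaN when total_fragments == 0

    def __post_init__(self) -> None:
        if self.total_fragments < 0:
            raise ValueError("total_fragments must be >= 0")
        if not np.isnan(self.frip) and not 0 <= self.frip <= 1:
            raise ValueError("frip must lie in [0, 1]")


def compute_atac_qc(
    fragments: pd.DataFrame,
    peaks: Sequence[Region],
    cells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-barcode total fragments and FrIP.

    FrIP = (count-weighted fragments overlapping any merged peak by
    >= 1 bp) / (count-weighted total fragments).  Merging makes the
    metric invariant to how an identical peak territory is split.
    ``cells`` adds barcodes that must appear even with no fragments;
    such cells have FrIP NaN (undefined) and are removed by
    :func:`filter_atac_cells`.
    """
    if len(peaks) == 0:
        warnings.warn("empty peak set: FrIP is 0 for all cells")
        in_peak = np.zeros(len(fragments), dtype=bool)
    else:
        in_peak = _peak_overlap_mask(
            fragments["chrom"].to_numpy(),
            fragments["start"].to_numpy(),
            fragments["end"].to_numpy(),
            peaks,
        )
    w = fragments["count"].to_numpy().astype(float)
    df = pd.DataFrame(
        {"barcode": fragments["barcode"].to_numpy(), "w": w, "hit": in_peak * w}
    )
    agg = df.groupby("barcode", sort=True).sum()
    if cells is not None:
        agg = agg.reindex(sorted(set(agg.index) | set(cells)), fill_value=0.0)
    total = agg["w"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frip = np.where(total > 0, agg["hit"].to_numpy() / total, np.nan)
    return pd.DataFrame(
        {
            "barcode": agg.index.to_numpy(),
            "total_fragments": total.astype(np.int64),
            "frip": frip,
        }
    ).reset_index(drop=True)


def filter_atac_cells(
    qc: pd.DataFrame, frip_min: float = 0.2, frag_min: int = 1000
) -> list[str]:
    """Barcodes kept by the accessibility QC filter.

    Removal is strict ("FrIP < frip_min or fragments < frag_min"), so
    boundary cells are retained.  Cells with undefined FrIP are removed.
    """
    frip = qc["frip"].to_numpy()
    keep = (~np.isnan(frip)) & (frip >= frip_min) & (qc["total_fragments"].to_numpy() >= frag_min)
    return list(qc["barcode"].to_numpy()[keep])


def filter_rna_cells(
    expression: pd.DataFrame,
    genes_min: int = 200,
    mito_max: float = 0.8,
    mito_prefix: str = "MT-",
) -> list[str]:
    """Cells kept by the snRNA filter (genes-by-cells UMI matrix).

    A cell is kept iff it expresses >= ``genes_min`` genes (UMI > 0)
    and at most ``mito_max`` of its UMIs come from mitochondrial genes
    (identified by name prefix).  Boundary cells are retained.
    """
    X = expression.to_numpy()
    n_genes = (X > 0).sum(axis=0)
    is_mito = expression.index.str.startswith(mito_prefix)
    if not is_mito.any():
        warnings.warn(f"no genes with prefix {mito_prefix!r}: mito filter skipped")
        mito_frac = np.zeros(X.shape[1])
    else:
        total = X.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, X[is_mito].sum(axis=0) / np.where(total > 0, total, 1), 0.0)
    keep = (n_genes >= genes_min) & (mito_frac <= mito_max)
    return list(expression.columns[keep])
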