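"""End-to-end drivers tying the pipeline stages together.

These are the entry points the analysis scripts, the CLI and the
acceptance checks share: simulate (or load) fragments, QC-filter
cells, build normalized off-target coverage, GC-corrected log2 fold
changes, clone clusters and promoter-based subtype labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import Region
from .cell_qc import compute_atac_qc, filter_atac_cells
from .clone_concordance import call_cell_labels, concordance, promoter_counts
from .cnv_inference import (
    GenomicWindows,
    cluster_cells_by_cnv,
    cnv_fold_change,
    correlate_profiles,
    effective_window_size,
    gc_matched_background,
    segment_profiles,
    window_coverage,
)
from .cnv_inference import make_windows, window_gc
from .genomic_io import GenomeModel
from .synthetic_data import SimulationConfig, simulate_fragments, simulate_gc_track

__all__ = ["cnv_profiles", "CloneRun", "run_clone_analysis"]


def cnv_profiles(
    fragments: pd.DataFrame,
    peaks: Sequence[Region],
    windows: GenomicWindows,
    grouping: Mapping[str, str] | None = None,
    n_match: int = 100,
    eps: float = 0.01,
) -> tuple[GenomicWindows, pd.DataFrame, pd.DataFrame]:
    """Off-target coverage and GC-corrected log2FC profiles.

    Returns ``(windows_with_effective_lengths, coverage, log2fc)``.
    """
    windows = effective_window_size(windows, peaks)
    coverage = window_coverage(fragments, windows, peaks, grouping)
    background = gc_matched_background(windows, n_match)
    log2fc = cnv_fold_change(coverage, background, windows, eps)
    return windows, coverage, log2fc


@dataclass
class CloneRun:
    """Everything a full synthetic clone analysis produces."""

    config: SimulationConfig
    fragments: pd.DataFrame
    truth_cells: pd.DataFrame
    peaks: list[Region]
    windows: GenomicWindows
    qc: pd.DataFrame
    kept_barcodes: list[str]
    coverage: pd.DataFrame
    log2fc: pd.DataFrame
    genetic_labels: pd.Series
    clone_log2fc: pd.DataFrame
    clone_coverage: pd.DataFrame
    clone_windows: GenomicWindows
    clone_segments: pd.DataFrame
    epigenetic_labels: pd.Series
    concordance: dict


def run_clone_analysis(
    config: SimulationConfig,
    k: int | None = None,
    kmeans_seed: int = 0,
    n_match: int = 100,
) -> CloneRun:
    """Simulate fragments and run QC -> CNV -> clones -> promoter labels.

    Clone-level (pseudobulk) profiles pool the fragments of each truth
    clone's QC-passing cells; per-cell profiles drive K-means with
    ``k`` defaulting to the number of planted clones.
    """
    fragments, truth_cells, peaks, windows = simulate_fragments(config)
    qc = compute_atac_qc(fragments, peaks)
    kept = filter_atac_cells(qc)
    frag_kept = fragments[fragments["barcode"].isin(set(kept))]

    windows, coverage, log2fc = cnv_profiles(frag_kept, peaks, windows, n_match=n_match)

    if k is None:
        k = len(config.clones)
    genetic = cluster_cells_by_cnv(log2fc, windows, k=k, seed=kmeans_seed)

    # clone-level (pseudobulk) profiles at 1 Mb resolution
    clone_of = dict(zip(truth_cells["barcode"], truth_cells["clone_id"]))
    grouping = {b: clone_of[b] for b in kept if b in clone_of}
    gc_track = simulate_gc_track(config)
    fine = window_gc(
        make_windows(GenomeModel(config.chrom_sizes), 1_000_000), gc_track=gc_track
    )
    fine, clone_coverage, clone_log2fc = cnv_profiles(
        frag_kept, peaks, fine, grouping=grouping, n_match=n_match
    )
    clone_segments = segment_profiles(clone_log2fc, fine)

    acc = promoter_counts(frag_kept, config.marker_promoters, cells=kept)
    epi = call_cell_labels(acc)
    conc = concordance(epi, genetic)

    return CloneRun(
        config=config,
        fragments=fragments,
        truth_cells=truth_cells,
        peaks=peaks,
        windows=windows,
        qc=qc,
        kept_barcodes=kept,
        coverage=coverage,
        log2fc=log2fc,
        genetic_labels=genetic,
        clone_log2fc=clone_log2fc,
        clone_coverage=clone_coverage,
        clone_windows=fine,
        clone_segments=clone_segments,
        epigenetic_labels=epi,
        concordance=conc,
    )
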