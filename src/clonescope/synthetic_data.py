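"""Synthetic scATAC fragment and expression generator with planted truth.

Emulates the statistical structure the downstream analysis assumes:

* a multi-chromosome genome tiled into windows with smoothly varying
  (spatially autocorrelated) GC fraction;
* a multi-clone cell population in which each clone carries planted
  megabase-scale copy-number events (integer copies on a diploid
  baseline) and an epigenetic subtype (ASCL1-like, NEUROD1-like, normal,
  or a mixture);
* per-cell fragment counts with a target fraction of fragments in peaks
  (FrIP) and off-target fragments placed per (cell, window) by Poisson
  draws with intensity proportional to copy_number x GC efficiency x
  effective window size;
* marker-promoter peaks (SOX2, INSM1, ASCL1, NEUROD1) whose per-cell
  accessibility follows tumor status and subtype, so promoter-based cell
  typing has a planted answer;
* a genes-by-samples expression matrix with two anti-correlated
  transcription-factor programs (ASCL1 / NEUROD1) of configurable
  log2 effect size, lognormal noise, and per-sample mixing weights.

Everything is deterministic under a fixed seed (numpy Generator,
PCG64).  Truth tables are first-class outputs so tests never reach into
simulator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomeModel, Region, write_bed, write_expression, write_fragments
from .cnv_inference import GenomicWindows, make_windows

__all__ = [
    "CNVEvent",
    "CloneTruth",
    "SimulationConfig",
    "simulate_genome",
    "simulate_gc_track",
    "simulate_fragments",
    "simulate_expression",
    "write_simulation",
    "default_clones",
]


@dataclass(frozen=True)
class CNVEvent:
    region: Region
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")


@dataclass
class CloneTruth:
    """One genetic clone: its CNV events, population fraction and subtype.

    ``subtype`` is either a single label ("normal", "ASCL1", "NEUROD1")
    or a mapping label -> probability for clones mixing two epigenetic
    subtypes within one genetic population.
    """

    clone_id: str
    events: list[CNVEvent] = field(default_factory=list)
    fraction: float = 1.0
    subtype: str | Mapping[str, float] = "normal"

    def subtype_probs(self) -> dict[str, float]:
        if isinstance(self.subtype, str):
            return {self.subtype: 1.0}
        total = sum(self.subtype.values())
        return {k: v / total for k, v in self.subtype.items()}


def default_clones() -> list[CloneTruth]:
    """The default three-population scenario.

    A normal diploid population, an ASCL1-subtype clone carrying a 20 Mb
    4-copy gain, and a NEUROD1-subtype clone carrying a 10 Mb single-copy
    loss — the scale of clone-distinguishing events the analysis targets.
    """
    return [
        CloneTruth("normal", [], 1 / 3, "normal"),
        CloneTruth(
            "cloneA",
            [CNVEvent(Region("chr2", 40_000_000, 60_000_000), 4)],
            1 / 3,
            "ASCL1",
        ),
        CloneTruth(
            "cloneB",
            [CNVEvent(Region("chr3", 100_000_000, 110_000_000), 1)],
            1 / 3,
            "NEUROD1",
        ),
    ]


def _default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 300_000_000 for i in range(1, 6)}


def _default_marker_promoters() -> dict[str, Region]:
    # placed on chr1, copy-neutral in every default clone
    return {
        "SOX2": Region("chr1", 10_000_000, 10_002_000, "SOX2"),
        "INSM1": Region("chr1", 20_000_000, 20_002_000, "INSM1"),
        "ASCL1": Region("chr1", 30_000_000, 30_002_000, "ASCL1"),
        "NEUROD1": Region("chr1", 40_000_000, 40_002_000, "NEUROD1"),
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    # genome / windows
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    window_size: int = 2_000_000
    gc_bin_size: int = 1_000_000
    gc_mean: float = 0.5
    gc_sd: float = 0.12
    gc_smooth_span: int = 7
    gc_range: tuple[float, float] = (0.30, 0.70)
    constant_gc: float | None = None
    # GC amplification-efficiency bias: efficiency = 1 + slope*(gc - 0.5)
    gc_bias_slope: float = 0.6
    # peaks / fragments
    n_peaks: int = 2000
    peak_width: int = 1000
    marker_promoters: dict[str, Region] = field(default_factory=_default_marker_promoters)
    marker_weight: float = 10.0
    fragments_per_cell: int = 16000
    frip_mean: float = 0.3
    frip_sd: float = 0.04
    fragment_length: tuple[int, int] = (50, 300)
    # population
    n_cells: int = 600
    clones: list[CloneTruth] = field(default_factory=default_clones)
    # expression
    n_program_genes: int = 50
    n_background_genes: int = 400
    effect_log2fc: float = 2.0
    expression_noise_sd: float = 0.5
    base_log2_expression: float = 5.0
    n_samples_a: int = 10
    n_samples_b: int = 10
    mixture_weights: tuple[float, ...] = ()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def validate(self) -> None:
        genome = GenomeModel(self.chrom_sizes)
        fr = sum(c.fraction for c in self.clones)
        if abs(fr - 1.0) > 1e-6:
            raise ValueError(f"clone fractions must sum to 1, got {fr}")
        for clone in self.clones:
            for ev in clone.events:
                genome.validate_region(ev.region)


# ---------------------------------------------------------------------------
# genome & GC

def simulate_gc_track(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-bin GC fractions (chrom, start, end, gc) at ``gc_bin_size``.

    GC is moving-average-smoothed white noise per chromosome (spatially
    autocorrelated), rescaled to the configured mean/SD and clipped to
    ``gc_range``; ``constant_gc`` overrides with a flat value.
    """
    rng = config.rng() if rng is None else rng
    genome = GenomeModel(dict(config.chrom_sizes))
    bins = make_windows(genome, config.gc_bin_size).table[["chrom", "start", "end"]].copy()
    if config.constant_gc is not None:
        bins["gc"] = config.constant_gc
        return bins
    gc = np.empty(len(bins))
    span = max(1, config.gc_smooth_span)
    kernel = np.ones(span) / span
    for chrom, grp in bins.groupby("chrom", sort=False):
        raw = rng.normal(0.0, 1.0, len(grp) + span)
        sm = np.convolve(raw, kernel, mode="same")[: len(grp)]
        sd = sm.std()
        if sd > 0:
            sm = (sm - sm.mean()) / sd
        gc[grp.index.to_numpy()] = config.gc_mean + config.gc_sd * sm
    bins["gc"] = np.clip(gc, *config.gc_range)
    return bins


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeModel, GenomicWindows, pd.DataFrame]:
    """Build the genome model, the analysis windows, and the GC track.

    The GC track is generated once at ``gc_bin_size`` resolution; window
    GC at any tiling is its length-weighted average, so analyses at
    different window sizes see a consistent GC landscape.
    """
    from .cnv_inference import window_gc

    rng = config.rng() if rng is None else rng
    genome = GenomeModel(dict(config.chrom_sizes))
    gc_track = simulate_gc_track(config, rng)
    windows = window_gc(make_windows(genome, config.window_size), gc_track=gc_track)
    return genome, windows, gc_track


def _gc_efficiency(gc: np.ndarray, slope: float) -> np.ndarray:
    return np.maximum(1.0 + slope * (gc - 0.5), 0.05)


def _clone_copy_vector(clone: CloneTruth, windows: GenomicWindows) -> np.ndarray:
    """Window copy numbers: the copy of the event containing the window midpoint."""
    table = windows.table
    copy = np.full(len(table), 2.0)
    mid = (table["start"].to_numpy() + table["end"].to_numpy()) // 2
    chrom = table["chrom"].to_numpy()
    for ev in clone.events:
        hit = (chrom == ev.region.chrom) & (mid >= ev.region.start) & (mid < ev.region.end)
        copy[hit] = ev.copy_number
    return copy


def _draw_frip(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd <= 0:
        return np.full(n, mean)
    var = sd**2
    m = mean * (1 - mean) / var - 1
    if m <= 0:
        raise ValueError("frip_sd too large for a Beta distribution at this mean")
    return rng.beta(mean * m, (1 - mean) * m, n)


def simulate_fragments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[Region], GenomicWindows]:
    """Generate a fragment table plus per-cell clone/subtype truth.

    Returns ``(fragments, truth_cells, peaks, windows)``.  Expected
    off-target coverage per (cell, window) is proportional to
    copy_number x GC efficiency x effective window size; in-peak
    fragments are distributed over peaks with marker promoters weighted
    per cell according to tumor status and subtype.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    genome, windows, gc_track = simulate_genome(config, rng)
    # fragment placement happens at GC-bin resolution so that coverage
    # carries the GC bias consistently at any analysis window size
    bins = GenomicWindows(
        gc_track.assign(
            effective_length=gc_track["end"] - gc_track["start"], usable=True
        )
    )
    table = bins.table
    n_win = len(table)
    gc_eff = _gc_efficiency(table["gc"].to_numpy(), config.gc_bias_slope)
    win_len = bins.lengths.astype(float)

    # --- peaks: random background peaks + fixed marker promoters
    peaks: list[Region] = []
    chroms = list(genome.lengths)
    chrom_lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    pchrom = rng.choice(len(chroms), size=config.n_peaks, p=chrom_lens / chrom_lens.sum())
    for ci in pchrom:
        start = int(rng.integers(0, genome.lengths[chroms[ci]] - config.peak_width))
        peaks.append(Region(chroms[ci], start, start + config.peak_width))
    marker_names = list(config.marker_promoters)
    marker_regions = [config.marker_promoters[m] for m in marker_names]
    all_peaks = peaks + marker_regions
    n_regular = len(peaks)

    # --- cells: clone memberships and subtypes
    fracs = np.array([c.fraction for c in config.clones])
    counts = np.floor(fracs * config.n_cells).astype(int)
    for i in np.argsort(-(fracs * config.n_cells - counts))[: config.n_cells - counts.sum()]:
        counts[i] += 1
    cell_clone: list[int] = []
    for i, c in enumerate(counts):
        if c == 0:
            import warnings

            warnings.warn(f"clone {config.clones[i].clone_id} received 0 cells; omitted")
        cell_clone += [i] * c
    cell_clone_arr = np.array(cell_clone)
    barcodes = [f"CELL{i:05d}-1" for i in range(config.n_cells)]
    subtypes = np.empty(config.n_cells, dtype=object)
    for ci, clone in enumerate(config.clones):
        idx = np.flatnonzero(cell_clone_arr == ci)
        probs = clone.subtype_probs()
        labels = list(probs)
        subtypes[idx] = rng.choice(labels, size=idx.size, p=[probs[l] for l in labels])

    copy_by_clone = np.stack([_clone_copy_vector(c, bins) for c in config.clones])

    # --- per-cell fragment budget
    frip_target = _draw_frip(rng, config.frip_mean, config.frip_sd, config.n_cells)
    n_total = np.full(config.n_cells, config.fragments_per_cell)
    n_inpeak = rng.binomial(n_total, frip_target)
    n_off = n_total - n_inpeak

    # --- off-target placement: Poisson per (cell, window)
    weight_by_clone = copy_by_clone / 2.0 * gc_eff[None, :] * (win_len / win_len.mean())[None, :]
    weight_by_clone /= weight_by_clone.sum(axis=1, keepdims=True)
    lam = n_off[:, None] * weight_by_clone[cell_clone_arr]
    off_counts = rng.poisson(lam)  # cells x windows

    cell_idx_off = np.repeat(np.arange(config.n_cells), off_counts.sum(axis=1))
    win_idx_off = np.concatenate(
        [np.repeat(np.arange(n_win), off_counts[c]) for c in range(config.n_cells)]
    ) if off_counts.sum() else np.empty(0, dtype=int)
    wstart = table["start"].to_numpy()[win_idx_off]
    wend = table["end"].to_numpy()[win_idx_off]
    lo, hi = config.fragment_length
    flen_off = rng.integers(lo, hi, size=win_idx_off.size)
    fstart_off = (wstart + rng.random(win_idx_off.size) * (wend - wstart - flen_off)).astype(np.int64)
    fchrom_off = table["chrom"].to_numpy()[win_idx_off]

    # --- in-peak placement: weighted choice of peak per fragment
    marker_on = {
        "SOX2": lambda st: st != "normal",
        "INSM1": lambda st: st != "normal",
        "ASCL1": lambda st: st == "ASCL1",
        "NEUROD1": lambda st: st == "NEUROD1",
    }
    peak_chrom = np.array([p.chrom for p in all_peaks], dtype=object)
    peak_start = np.array([p.start for p in all_peaks])
    peak_end = np.array([p.end for p in all_peaks])
    in_cell_idx = []
    in_peak_idx = []
    for st in np.unique(subtypes):
        cells = np.flatnonzero(subtypes == st)
        w = np.ones(len(all_peaks))
        for mi, mname in enumerate(marker_names):
            on = marker_on.get(mname, lambda s: s != "normal")(st)
            w[n_regular + mi] = config.marker_weight if on else 0.0
        p = w / w.sum()
        tot = int(n_inpeak[cells].sum())
        if tot == 0:
            continue
        draws = rng.choice(len(all_peaks), size=tot, p=p)
        in_peak_idx.append(draws)
        in_cell_idx.append(np.repeat(cells, n_inpeak[cells]))
    if in_cell_idx:
        cell_idx_in = np.concatenate(in_cell_idx)
        peak_idx_in = np.concatenate(in_peak_idx)
    else:
        cell_idx_in = np.empty(0, dtype=int)
        peak_idx_in = np.empty(0, dtype=int)
    flen_in = rng.integers(lo, hi, size=cell_idx_in.size)
    span = np.maximum(peak_end[peak_idx_in] - peak_start[peak_idx_in] - 1, 1)
    fstart_in = (peak_start[peak_idx_in] + rng.random(cell_idx_in.size) * span).astype(np.int64)
    fchrom_in = peak_chrom[peak_idx_in]

    barcode_arr = np.array(barcodes, dtype=object)
    fragments = pd.DataFrame(
        {
            "chrom": np.concatenate([fchrom_off, fchrom_in]),
            "start": np.concatenate([fstart_off, fstart_in]),
            "end": np.concatenate([fstart_off + flen_off, fstart_in + flen_in]),
            "barcode": barcode_arr[np.concatenate([cell_idx_off, cell_idx_in])],
            "count": np.ones(cell_idx_off.size + cell_idx_in.size, dtype=np.int64),
        }
    )
    fragments = fragments.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    truth_cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "clone_id": [config.clones[c].clone_id for c in cell_clone_arr],
            "subtype": subtypes,
            "frip_target": frip_target,
        }
    )
    return fragments, truth_cells, all_peaks, windows


def truth_events_table(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (c.clone_id, ev.region.chrom, ev.region.start, ev.region.end, ev.copy_number)
        for c in config.clones
        for ev in c.events
    ]
    return pd.DataFrame(rows, columns=["clone_id", "chrom", "start", "end", "copy_number"])


# ---------------------------------------------------------------------------
# expression

def program_genes(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Gene names of the two TF programs; marker TFs are members."""
    n = config.n_program_genes
    a = ["ASCL1"] + [f"ASC_TG{i:03d}" for i in range(1, n)]
    b = ["NEUROD1"] + [f"NDR_TG{i:03d}" for i in range(1, n)]
    return a, b


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes-by-samples expression with two anti-correlated programs.

    Each sample carries a mixing weight ``w``: program-A genes have
    log2 mean ``base + effect*w``, program-B genes ``base + effect*(1-w)``,
    background genes ``base``; lognormal noise of the configured SD (in
    log2 units) is added and values are returned on the linear (TPM-like)
    scale.  Pure A-type samples have w=1, pure B-type w=0.
    """
    rng = config.rng() if rng is None else rng
    genes_a, genes_b = program_genes(config)
    background = [f"BG_{i:04d}" for i in range(config.n_background_genes)]
    genes = genes_a + genes_b + background

    weights = (
        [1.0] * config.n_samples_a + [0.0] * config.n_samples_b + list(config.mixture_weights)
    )
    labels = (
        ["ASCL1"] * config.n_samples_a
        + ["NEUROD1"] * config.n_samples_b
        + ["mixed"] * len(config.mixture_weights)
    )
    samples = [f"S{i:03d}" for i in range(len(weights))]
    w = np.asarray(weights)

    base = config.base_log2_expression + rng.normal(0.0, 1.0, len(genes))  # per-gene offset
    log2x = np.tile(base[:, None], (1, len(samples)))
    na, nb = len(genes_a), len(genes_b)
    log2x[:na] += config.effect_log2fc * w[None, :]
    log2x[na : na + nb] += config.effect_log2fc * (1.0 - w)[None, :]
    log2x += rng.normal(0.0, config.expression_noise_sd, log2x.shape)
    expr = pd.DataFrame(np.power(2.0, log2x), index=genes, columns=samples)
    truth = pd.DataFrame({"sample": samples, "subtype": labels, "weight": weights})
    return expr, truth


# ---------------------------------------------------------------------------
# file output

def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the generator and write every artifact as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fragments, truth_cells, peaks, windows = simulate_fragments(config)
    gc_track = simulate_gc_track(config)
    expr, expr_truth = simulate_expression(config)
    paths = {
        "fragments": outdir / "fragments.tsv.gz",
        "peaks": outdir / "peaks.bed",
        "gc": outdir / "gc.bedGraph",
        "truth_cells": outdir / "truth_cells.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "chrom_sizes": outdir / "genome.chrom.sizes",
    }
    write_fragments(fragments, paths["fragments"])
    write_bed(peaks, paths["peaks"])
    gc_track.to_csv(paths["gc"], sep="\t", header=False, index=False)
    truth_cells.to_csv(paths["truth_cells"], sep="\t", index=False)
    truth_events_table(config).to_csv(paths["truth_events"], sep="\t", index=False)
    write_expression(expr, paths["expression"])
    expr_truth.to_csv(paths["labels"], sep="\t", index=False)
    with open(paths["chrom_sizes"], "w") as fh:
        for name, size in config.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")
    return paths
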