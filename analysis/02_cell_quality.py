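#!/usr/bin/env python
"""Per-cell quality control of the simulated scATAC fragments.

Computes total fragments and FrIP per barcode and applies the
inclusion filter (FrIP >= 0.2 and >= 1000 fragments).  Reads the
fragment file written by 01_simulate_cohort.py; writes results/qc.tsv.
"""

from pathlib import Path

from clonescope.cell_qc import compute_atac_qc, filter_atac_cells
from clonescope.genomic_io import read_bed, read_chrom_sizes, read_fragments_frame

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    genome = read_chrom_sizes(SIM / "genome.chrom.sizes")
    fragments = read_fragments_frame(SIM / "fragments.tsv.gz", genome)
    peaks = read_bed(SIM / "peaks.bed")
    qc = compute_atac_qc(fragments, peaks)
    kept = set(filter_atac_cells(qc))
    qc["kept"] = qc["barcode"].isin(kept)
    RESULTS.mkdir(exist_ok=True)
    qc.to_csv(RESULTS / "qc.tsv", sep="\t", index=False)
    print(f"{len(kept)} / {len(qc)} cells pass QC "
          f"(median FrIP {qc['frip'].median():.3f}, "
          f"median fragments {int(qc['total_fragments'].median())})")


if __name__ == "__main__":
    main()
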