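import numpy as np
import pytest
from hypothesis import settings

from clonescope import SimulationConfig
from clonescope.genomic_io import Region
from clonescope.synthetic_data import CloneTruth, CNVEvent
from clonescope.pipeline import run_clone_analysis

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(**overrides) -> SimulationConfig:
    """A fast two-chromosome configuration for unit-scale simulations."""
    defaults = dict(
        seed=5,
        chrom_sizes={"chr1": 60_000_000, "chr2": 60_000_000},
        n_cells=30,
        fragments_per_cell=2000,
        n_peaks=200,
        clones=[CloneTruth("normal", [], 1.0, "normal")],
        marker_promoters={
            "SOX2": Region("chr1", 5_000_000, 5_002_000, "SOX2"),
            "INSM1": Region("chr1", 10_000_000, 10_002_000, "INSM1"),
            "ASCL1": Region("chr1", 15_000_000, 15_002_000, "ASCL1"),
            "NEUROD1": Region("chr1", 20_000_000, 20_002_000, "NEUROD1"),
        },
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def two_clone_config(**overrides) -> SimulationConfig:
    """Small config with one gain clone and one normal clone."""
    clones = [
        CloneTruth("normal", [], 0.5, "normal"),
        CloneTruth(
            "gain", [CNVEvent(Region("chr2", 20_000_000, 40_000_000), 4)], 0.5, "ASCL1"
        ),
    ]
    return small_config(clones=clones, **overrides)


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition analysis shared by the slower tests."""
    return run_clone_analysis(SimulationConfig(seed=1), kmeans_seed=7)
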