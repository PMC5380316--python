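import numpy as np
import pytest

from admixtime import GeneticMap, PulseModel, simulate_pulse_tracks


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Three chromosomes with SNPs, small enough for fast pipelines."""
    return GeneticMap.uniform({"1": 150.0, "2": 130.0, "3": 120.0},
                              snps_per_cm=4.0)


@pytest.fixture(scope="session")
def long_chromosome_map() -> GeneticMap:
    """One long chromosome: edge-truncation effects are negligible."""
    return GeneticMap(lengths_cm={"1": 5000.0})


@pytest.fixture(scope="session")
def pulse_tracks_5050(long_chromosome_map):
    model = PulseModel({"EU": 0.5, "ME": 0.5}, t=30)
    return simulate_pulse_tracks(long_chromosome_map, model, 40, seed=42)


def stacked_positions(gmap: GeneticMap) -> np.ndarray:
    """Concatenated cM positions with 1000-cM chromosome offsets (so windows
    never straddle chromosomes)."""
    out = []
    off = 0.0
    for c in gmap.chromosomes:
        out.append(gmap.positions_cm[c] + off)
        off += 1000.0
    return np.concatenate(out)
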