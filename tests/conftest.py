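import numpy as np
import pandas as pd
import pytest

from persistqtl import sim


def make_map(markers_per_chrom, spacing=10_000, start=5_000):
    """Small hand-built marker map: {chrom: n_markers} at fixed spacing."""
    rows = []
    for chrom, n in markers_per_chrom.items():
        for i in range(n):
            pos = start + i * spacing
            rows.append((f"c{chrom}m{i}", chrom, pos))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])


@pytest.fixture(scope="session")
def small_map():
    return sim.make_marker_map(64, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_map):
    return sim.simulate_cross(small_map, 150, 3.0, seed=12)


@pytest.fixture(scope="session")
def mapping_map():
    return sim.make_marker_map(256, seed=21)


@pytest.fixture(scope="session")
def mapping_genotypes(mapping_map):
    return sim.simulate_cross(mapping_map, 400, 3.0, seed=22)
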