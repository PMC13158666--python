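"""Shared synthetic fixtures.

Everything is generated programmatically; session scope keeps the heavier
tissues to a single construction per run.
"""

import numpy as np
import pandas as pd
import pytest

from insituprox.simulate import SimulationConfig, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """A null two-type tissue used by spatial/stat unit tests."""
    cfg = SimulationConfig(
        n_cells=150, n_genes=30, extent_um=(150, 150, 25),
        type_proportions={"tumor": 0.55, "T_cell": 0.45},
        marker_genes_per_type=2,
    )
    sample, truth = generate_tissue(cfg, seed=101)
    return sample, truth


@pytest.fixture(scope="session")
def five_type_tissue():
    """A null five-type tissue at the default study conditions (reduced
    panel for runtime)."""
    cfg = SimulationConfig(n_cells=400, n_genes=60)
    sample, truth = generate_tissue(cfg, seed=202)
    return sample, truth


@pytest.fixture()
def tiny_transcripts():
    """Hand-written 2-cell transcript table (3 assigned molecules)."""
    return pd.DataFrame({
        "gene": ["g1", "g2", "g1", "g3"],
        "x": [0.0, 3.0, 1.0, 50.0],
        "y": [0.0, 4.0, 0.0, 50.0],
        "z": [0.0, 0.0, 0.0, 0.0],
        "cell_id": ["a", "a", "b", ""],
        "fov_id": ["f0", "f0", "f0", "f0"],
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
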