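import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mkptools.simulate import SimConfig, generate_multimodal

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest multimodal dataset shared across read-only tests."""
    return generate_multimodal(SimConfig(n_cells=800, n_genes=120, seed=11))


@pytest.fixture(scope="session")
def small_clr(small_dataset):
    from mkptools.normalize import clr_normalize_matrix

    return clr_normalize_matrix(small_dataset.adt_frame())


@pytest.fixture()
def toy_deg_table():
    """Six-gene DEG table exercising every filter rule."""
    return pd.DataFrame(
        {
            "log2FC": [2.6, 2.6, 1.6, 0.1, 3.0, 4.0],
            "padj": [0.005, 0.02, 0.5, 0.001, np.nan, 1e-6],
            "baseMean_A": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            "baseMean_B": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            "blocklist_category": ["none", "none", "none", "none", "none", "mito"],
        },
        index=["g1", "g2", "g3", "g4", "g5", "mt-Co1"],
    )
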