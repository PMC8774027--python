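import numpy as np
import pandas as pd
import pytest

from cytometa import SimulationConfig, simulate_bulk, simulate_reference


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """Three small studies, 300 genes: fast but structurally complete."""
    return SimulationConfig(
        n_studies=3,
        n_per_group=((8, 8), (10, 6), (7, 9)),
        n_genes=300,
        n_markers_per_type=8,
        n_true_degs=10,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    ref = simulate_reference(tiny_cfg)
    data, truth = simulate_bulk(tiny_cfg, ref)
    return ref, data, truth


@pytest.fixture()
def toy_specificity() -> pd.DataFrame:
    """500-gene random specificity matrix over 4 types; the first 20 genes
    are fully specific to type T1."""
    rng = np.random.default_rng(99)
    s = rng.dirichlet(np.ones(4), 500).T
    s[:, :20] = 0.0
    s[0, :20] = 1.0
    return pd.DataFrame(
        s, index=["T1", "T2", "T3", "T4"], columns=[f"g{i:03d}" for i in range(500)]
    )
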