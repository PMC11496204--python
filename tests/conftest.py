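import numpy as np
import pandas as pd
import pytest

import ploidyscreen as ps
from ploidyscreen.config import DesignCell


@pytest.fixture(scope="session")
def small_dataset():
    """One site/cohort/dam cell, 2 individuals per ploidy, moderate noise."""
    config = ps.SimulationConfig(
        n_genes=1200,
        design=[DesignCell("siteA", "cohX", "dam1", n_per_ploidy=2)],
        dispersion=50.0,
        lib_size_mean=200_000,
        lib_size_cv=0.1,
        covariate_effect_sd=0.1,
        seed=42,
    )
    return ps.simulate_dataset(config)


@pytest.fixture(scope="session")
def study_samples():
    """Sample table for the full 2 sites x 2 cohorts x 3 dams x 8 design."""
    from ploidyscreen.simulate import build_sample_table

    return build_sample_table(ps.SimulationConfig())


@pytest.fixture
def toy_counts():
    """Tiny hand-written count matrix: 3 genes x 2 samples."""
    return pd.DataFrame(
        {"s1": [10, 990, 0], "s2": [250, 250, 500]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
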