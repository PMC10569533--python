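import numpy as np
import pandas as pd
import pytest

from mutcr.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small single-type cohort shared by fast unit tests."""
    cfg = SimulationConfig(n_regions=400, p_motifs=30, n_contexts=2,
                           total_mutation_target=40_000, noise_sd=0.1,
                           spike_fraction=0.05, spike_multiplier=3.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_segmentation():
    return pd.DataFrame({
        "region_id": [0, 1, 2],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [0, 2000, 0],
        "end": [2000, 5000, 1500],
        "state": ["Quies", "TssA", "Enh"],
        "length_bp": [2000, 3000, 1500],
    })
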