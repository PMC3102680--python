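import numpy as np
import pytest

from phosphopath.quant import ComparisonSpec
from phosphopath.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Mid-sized seeded dataset with planted peptide effects, one active
    pathway and class-exclusive detections; shared across tests."""
    cfg = SimulationConfig(
        n_proteins=80,
        n_regulated=30,
        effect_size_log2=2.0,
        n_active_pathways=1,
        n_pathways=12,
        members_per_pathway=8,
        class_exclusive_fraction=0.05,
        replicate_noise_sd=0.15,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def comparison_3ktr():
    return ComparisonSpec("3KTR", "3KT")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
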