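import pytest

from methexpress.synthetic import (SimConfig, plant_interaction_gene,
                                   simulate_dataset)


@pytest.fixture(scope="session")
def planted_dataset():
    """200-gene dataset with 20 NR5A1-like interaction genes planted."""
    plants = [plant_interaction_gene(f"NM_{g:05d}", -0.3, 0.3, logfc=2.0)
              for g in range(20)]
    return simulate_dataset(SimConfig(seed=7), plants), plants


@pytest.fixture(scope="session")
def null_dataset():
    """Simulator defaults with no planted effects."""
    return simulate_dataset(SimConfig(seed=42))
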