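import numpy as np
import pandas as pd
import pytest

from ruminet.diffexpr import SampleDesign
from ruminet.simulate import ModuleSpec, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene dataset with 20 planted DE genes and one tight module."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=200,
        de_fraction=0.1,
        noise_sd=0.1,
        modules=(ModuleSpec(size=5, latent_sd=0.5, residual_sd=0.0),),
        n_categories=20,
        category_size_range=(5, 20),
        de_enrichment_boost=10.0,
        boosted_fraction=0.1,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-written 3-gene matrix over 3 + 4 samples with known group means."""
    samples = ["a1", "a2", "a3", "b1", "b2", "b3", "b4"]
    values = np.array(
        [
            [8.0, 8.0, 8.0, 10.0, 10.0, 10.0, 10.0],  # log2fc = +2
            [9.0, 9.0, 9.0, 9.0, 9.0, 9.0, 9.0],      # log2fc = 0
            [7.0, 7.0, 7.0, 5.5, 5.5, 5.5, 5.5],      # log2fc = -1.5
        ]
    )
    matrix = pd.DataFrame(values, index=["g1", "g2", "g3"], columns=samples)
    design = SampleDesign({s: ("A" if s.startswith("a") else "B") for s in samples})
    return matrix, design
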