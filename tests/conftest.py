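import numpy as np
import pytest

from gseacmap import PipelineConfig, SimConfig, generate_scenario


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted scenario shared by fast unit tests."""
    cfg = SimConfig(n_genes=500, n_sets=20, set_size_min=10, set_size_max=60,
                    n_compounds=6, n_classes=3, instances_per_compound=2,
                    fraction_de=0.08, seed=11)
    counts, genesets, reference, truth = generate_scenario(cfg)
    return cfg, counts, genesets, reference, truth


@pytest.fixture()
def fast_config():
    """Pipeline config with the permutation count at its floor for speed."""
    return PipelineConfig(n_perm=100, seed=11)


@pytest.fixture()
def default_config():
    return PipelineConfig(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
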