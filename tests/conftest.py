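import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from woundage.pipeline import run_synthetic_study
from woundage.synthetic import SimulationConfig, generate_gene_panel


@pytest.fixture(scope="session")
def default_panel():
    return generate_gene_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_study():
    """A quantified synthetic study at the default design (seed 1)."""
    return run_synthetic_study(seed=1)


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-noise study: no between-animal or technical variation."""
    sim = SimulationConfig(
        subgroup_sigma={s: 0.0 for s in
                        ("ARE-CC", "ARE-BP", "ARE-MF", "ARE+CC", "ARE+BP", "ARE+MF")},
        technical_sd=0.0,
        reference_sigma=0.0,
    )
    return run_synthetic_study(seed=2, simulation=sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)
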