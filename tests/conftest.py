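import numpy as np
import pytest
from hypothesis import settings

import irlpair as il

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

SMALL_CONFIG = il.SimulationConfig(
    n_tumor=150, n_normal=25, n_lnc=60, n_immune_genes=25, n_other_mrna=30,
    n_immune_linked=30, n_de=16, n_planted_pairs=3,
    planted_betas=(1.0, 0.8, 0.6), seed=42,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-size cohort with 3 planted prognostic pairs."""
    return il.simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Full pipeline result on the small cohort."""
    c = small_cohort
    return il.run_pipeline(c.expression, c.annotation, c.clinical,
                           c.immune_symbols, c.groups,
                           il.PipelineConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
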