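import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gwaspost import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    return sim.SimulationConfig(
        seed=42, n_variants=200, n_blocks=10, block_rho=0.5, n_causal=4,
        causal_beta_sd=0.06, n_studies=3,
        per_study_cases=30000, per_study_controls=90000,
    )


@pytest.fixture
def small_panel(small_config):
    return sim.simulate_ld_panel(small_config)


@pytest.fixture
def small_truth(small_panel, small_config):
    return sim.simulate_truth(small_panel, small_config)


@pytest.fixture
def small_stats(small_panel, small_truth, small_config):
    return sim.simulate_summary_stats(small_panel, small_truth, small_config)


def make_panel(eaf, R, chrom="1", pos_step=10_000):
    """Hand-build an LDPanel for targeted unit tests."""
    eaf = np.asarray(eaf, dtype=float)
    n = len(eaf)
    variants = pd.DataFrame(
        {
            "RSID": [f"rs{i + 1}" for i in range(n)],
            "CHR": chrom,
            "POS": 10_000 + pos_step * np.arange(n),
            "EA": "A",
            "NEA": "G",
            "EAF": eaf,
        }
    )
    return sim.LDPanel(variants=variants, R=np.asarray(R, float),
                       blocks=np.zeros(n, dtype=int))


@pytest.fixture
def panel_factory():
    return make_panel
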