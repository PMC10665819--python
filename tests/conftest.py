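import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metanet.stats import GROUPS, MetaboliteTable
from metanet.synthetic import (
    SyntheticConfig,
    corrected_pair_factor,
    make_toy_model,
    opposite_pair_factor,
    simulate_metabolite_table,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_model():
    model, truth = make_toy_model(seed=1)
    return model, truth


@pytest.fixture()
def small_table():
    """A tiny three-group table with hand-enterable values."""
    rng = np.random.default_rng(42)
    samples = [f"{g}_{i}" for g in GROUPS for i in range(5)]
    data = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=0.4, size=(15, 6)),
        index=samples,
        columns=[f"M{i+1:02d}" for i in range(6)],
    )
    groups = pd.Series([g for g in GROUPS for _ in range(5)], index=samples)
    return MetaboliteTable(data=data, groups=groups)


@pytest.fixture(scope="session")
def pattern_config():
    """Generator settings implanting one pair of each correlation class."""

    def make(seed, n_per_group=500):
        return SyntheticConfig(
            seed=seed,
            n_per_group=n_per_group,
            n_metabolites=6,
            latent_factors=[
                opposite_pair_factor("M01", "M02"),
                corrected_pair_factor("M03", "M04"),
            ],
        )

    return make


@pytest.fixture(scope="session")
def pattern_table(pattern_config):
    table, truth = simulate_metabolite_table(pattern_config(seed=11))
    return table, truth
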