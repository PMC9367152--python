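"""Shared fixtures: one small simulated cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import methstrata as ms
from methstrata.containers import MethylationMatrix


@pytest.fixture(scope="session")
def small_config() -> ms.SimulationConfig:
    return ms.SimulationConfig(
        n_train=220, n_test=130, m_probes=1200, batch_count=4, seed=42,
        trait_specs=[
            ms.TraitSpec.age_like(),
            ms.TraitSpec.complex_like("complex_1", h2m=0.6, n_causal=120),
            ms.TraitSpec.biochemical_like("biochem_1", h2m=0.441, n_causal=60),
        ])


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ms.Cohort:
    return ms.make_cohort(small_config)


@pytest.fixture(scope="session")
def train_residualized(small_cohort) -> MethylationMatrix:
    return ms.residualize_probes(small_cohort.train.methylation,
                                 small_cohort.train.phenotypes.covariates())


@pytest.fixture(scope="session")
def train_stats(small_cohort) -> pd.DataFrame:
    return ms.compute_probe_stats(small_cohort.train.methylation)


@pytest.fixture(scope="session")
def iid_matrix() -> MethylationMatrix:
    """Residualized-state matrix of iid normal probes (n=150, m=400)."""
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(rng.standard_normal((150, 400)),
                        index=[f"s{i:03d}" for i in range(150)],
                        columns=[f"p{j:03d}" for j in range(400)])
    return MethylationMatrix(vals, state="residualized")
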