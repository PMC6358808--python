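import numpy as np
import pytest

from metapair import (
    CohortConfig,
    filter_metabolites,
    flag_out_of_range,
    generate_cohort,
    null_cohort,
    within_pair_transform,
)

SMALL_PANEL = (("amino acids", 8, 8), ("biogenic amines", 4, 3))


@pytest.fixture(scope="session")
def default_cohort():
    """One default 32-pair cohort with the full 188-metabolite panel."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_null_cohort():
    return null_cohort(CohortConfig(seed=13))


@pytest.fixture(scope="session")
def filtered_null_data(default_null_cohort):
    """Within-pair transformed, quantitation-filtered null data."""
    cohort, matrix = default_null_cohort
    filtered, _ = filter_metabolites(flag_out_of_range(matrix))
    X = within_pair_transform(
        filtered.values.to_numpy(float), cohort.pair_ids.to_numpy())
    return cohort, filtered, X


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def small_config(seed: int, n_pairs: int = 16) -> CohortConfig:
    """Small panel config for simulation-heavy tests."""
    return CohortConfig(n_pairs=n_pairs, panel_spec=SMALL_PANEL, seed=seed)
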