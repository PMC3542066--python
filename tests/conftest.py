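import numpy as np
import pytest

from phosvar import (
    SimulationConfig,
    flank_analysis,
    make_worked_example,
    simulate_dataset,
    structure_categories,
    variability,
)


@pytest.fixture(scope="session")
def worked():
    """Tiny hand-checkable dataset: 3 proteins, 10 sites."""
    return make_worked_example()


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset under the default study conditions (5,173 sites)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def classified_default(default_dataset):
    """Default dataset taken through completeness filter, variability,
    structural classification and flank-window extraction."""
    ds = default_dataset
    table = variability.add_variability(variability.filter_complete(ds.site_table))
    classified = structure_categories.classify_sites(table, ds.profiles)
    return flank_analysis.add_flank_windows(classified, ds.sequences)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
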