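import numpy as np
import pytest
from hypothesis import settings

import atcmark as am

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """300-gene cohort, test-cohort class sizes, 5 spiked markers + 4 decoys."""
    cfg = am.SimulationConfig(n_genes=300, n_spiked_markers=5, n_decoy_markers=4, seed=1)
    counts, sheet, truth = am.simulate_counts(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture(scope="session")
def small_de(small_cohort):
    """Fitted ATC-vs-rest exact test on the small cohort."""
    _, counts, sheet, _ = small_cohort
    est = am.NBExactTest().fit(counts.T, sheet["class"].to_numpy())
    return est


@pytest.fixture(scope="session")
def atc_groups(small_cohort):
    _, _, sheet, _ = small_cohort
    return np.where(sheet["class"].to_numpy() == "ATC", "ATC", "noATC")
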