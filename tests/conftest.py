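import numpy as np
import pandas as pd
import pytest

from genediet.simulate import EffectConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 347-subject synthetic cohort (fixed seed)."""
    return simulate_cohort(SimulationConfig(n=347, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects, for calibration-style checks."""
    return simulate_cohort(SimulationConfig(n=500, seed=11, effects=EffectConfig.null()))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def brute_force_quantile_groups(values, k):
    """Independent sort-and-bucket oracle: group i holds values strictly above
    the (i-1)/k quantile and at or below the i/k quantile (ties go low)."""
    values = np.asarray(values, dtype=float)
    cuts = np.quantile(values, [i / k for i in range(1, k)])
    ranks = np.empty(len(values), dtype=int)
    for j, v in enumerate(values):
        r = 1
        for c in cuts:
            if v > c:
                r += 1
        ranks[j] = r
    return ranks
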