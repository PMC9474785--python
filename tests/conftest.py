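import numpy as np
import pytest

import extravaquant as eq


@pytest.fixture(scope="session")
def noiseless_cohort():
    """24-subject noiseless cohort with phantoms (shared; do not mutate)."""
    config = eq.CohortConfig().noiseless()
    pairs, studies, truths = eq.generate_cohort(config, seed=7)
    return config, pairs, studies, truths


@pytest.fixture(scope="session")
def noisy_cohort():
    """24-subject cohort under the default noise model (shared)."""
    config = eq.CohortConfig()
    pairs, studies, truths = eq.generate_cohort(config, seed=42)
    return config, pairs, studies, truths


@pytest.fixture()
def exp_diff():
    """Noiseless decaying-exponential difference TAC and its parameters."""
    t = np.arange(0.0, 3600.0)
    amp, rate = 2000.0, 0.001
    rates = amp * np.exp(-rate * t)
    return eq.Tac(t, rates, decay_corrected=True), amp, rate
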