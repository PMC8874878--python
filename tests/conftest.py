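import numpy as np
import pytest

import revlearn as rl


@pytest.fixture(scope="session")
def default_schedule():
    return rl.make_schedule()


@pytest.fixture(scope="session")
def small_schedule():
    """A short 40-trial session with a single reversal, for cheap fits."""
    cfg = rl.TaskConfig(
        n_trials=40, phase_lengths=(20, 10, 10), segment_lengths_reversal=(10,)
    )
    return rl.make_schedule(cfg)


@pytest.fixture(scope="session")
def idu_session(default_schedule):
    """One seeded session simulated from the iDU one-rate model."""
    params = rl.ParamSet(alpha=0.45, kappa=0.35, beta=6.0)
    rng = np.random.default_rng(42)
    return rl.simulate_agent(params, rl.spec_from_name("iDU-1a"), default_schedule, rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort for pipeline-level tests."""
    spec = rl.CohortSpec(n_per_group=(4, 4), seed=7)
    return rl.generate_cohort(spec)
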