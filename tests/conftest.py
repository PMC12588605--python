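import numpy as np
import pytest

from rhythmoscan.synthetic_data import (
    DesignConfig, ObserverParams, RhythmComponent, generate_design,
    simulate_observer,
)
from rhythmoscan.trial_data import filter_outliers, reference_delays, transform_rt


def prepared_cohort(n_participants, observer_kwargs=None, seed=0,
                    experiment="exp1", n_blocks=None, trials_per_block=None):
    """Simulate a cohort and run the standard preparation chain."""
    tables = []
    for i in range(n_participants):
        cfg = DesignConfig(experiment=experiment, seed=seed + 1000 * i,
                           participant_id=f"p{i:02d}", n_blocks=n_blocks,
                           trials_per_block=trials_per_block)
        obs = ObserverParams(**(observer_kwargs or {}))
        t = simulate_observer(generate_design(cfg), obs, seed=seed + 1000 * i + 1)
        tables.append(reference_delays(transform_rt(filter_outliers(t))))
    return tables


@pytest.fixture(scope="session")
def rhythmic_cohort():
    """Ten observers with a strong shared 4 Hz sensitivity rhythm."""
    rhythm = [RhythmComponent("dprime", 4.0, 1.2)]
    return prepared_cohort(10, dict(d0=1.5, rhythm=rhythm, lapse_rate=0.0), seed=7)


@pytest.fixture(scope="session")
def flat_cohort():
    """Ten observers with constant sensitivity (no rhythm)."""
    return prepared_cohort(10, dict(d0=1.5, lapse_rate=0.0), seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
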