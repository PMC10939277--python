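import numpy as np
import pytest

from flowparse.observer import (
    PopulationSpec,
    PredictionDesign,
    SpeedDesign,
    _draw_observers,
    simulate_prediction_experiment,
    simulate_speed_experiment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A 8-participant cohort with default generative effects, both tasks.

    Shared across tests that only need a realistic synthetic dataset, not a
    particular effect size.
    """
    pop = PopulationSpec()
    rng = np.random.default_rng(555)
    n = 8
    observers = _draw_observers(pop, n, rng)
    pred = simulate_prediction_experiment(
        PredictionDesign(n_participants=n, repetitions=5), pop, rng, observers=observers
    )
    speed = simulate_speed_experiment(
        SpeedDesign(n_participants=n), pop, rng, observers=observers
    )
    return {"pop": pop, "observers": observers, "prediction": pred, "speed": speed}
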