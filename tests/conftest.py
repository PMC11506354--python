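import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from vesselbehav import generate_survey, make_blocks, segment_events
from vesselbehav.synthetic_survey import SimulationConfig


def small_config(**overrides) -> SimulationConfig:
    """A compact survey: short sessions, frequent sightings."""
    from vesselbehav.synthetic_survey import DurationModel

    defaults = dict(
        n_sessions=4,
        session_length=150,
        sighting_hazard=0.10,
        duration=DurationModel(min_minutes=2, mean_minutes=18.0, max_minutes=60),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def random_small_config(rng: np.random.Generator) -> SimulationConfig:
    """Randomized generator settings to diversify oracle-equivalence runs."""
    from vesselbehav.synthetic_survey import DurationModel, VesselProcess

    return small_config(
        n_sessions=int(rng.integers(1, 4)),
        session_length=int(rng.integers(60, 200)),
        sighting_hazard=float(rng.uniform(0.05, 0.3)),
        vessel=VesselProcess(
            p_arrive=float(rng.uniform(0.0, 0.8)),
            p_leave=float(rng.uniform(0.1, 0.9)),
        ),
        duration=DurationModel(
            min_minutes=2,
            mean_minutes=float(rng.uniform(8, 30)),
            max_minutes=int(rng.integers(30, 132)),
        ),
        tick_state_noise=float(rng.choice([0.0, 0.15, 0.3])),
    )


@pytest.fixture(scope="session")
def medium_events():
    """A moderately sized segmented survey shared across tests."""
    cfg = small_config(n_sessions=60, sighting_hazard=0.08)
    records = generate_survey(cfg, seed=424242)
    return segment_events(make_blocks(records))
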