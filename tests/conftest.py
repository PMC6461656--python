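import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene():
    from earwound.sim import make_scene
    return make_scene(seed=42, n_arteries=1)


@pytest.fixture(scope="session")
def sprouts(scene):
    from earwound.sim import assign_perfusion, simulate_sprouting
    sp = simulate_sprouting(scene, [3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 8.0], seed=5)
    return assign_perfusion(sp, seed=6)


@pytest.fixture(scope="session")
def control_table():
    """Ground-truth cohort table for the default control arm, seed 42."""
    from earwound.sim import simulate_cohort
    table, _ = simulate_cohort(groups={"control": 10}, seed=42)
    return table


@pytest.fixture(scope="session")
def four_group_table():
    from earwound.sim import simulate_cohort
    table, _ = simulate_cohort(seed=42, with_calcium=False)
    return table


@pytest.fixture(scope="session")
def roi_set(scene):
    from earwound.imaging import place_rois
    return place_rois(scene, 256)
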