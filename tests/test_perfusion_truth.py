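import numpy as np
import pytest

from earwound.sim import (DomainError, assign_perfusion, is_censored,
                          simulate_perfusion_truth, simulate_sprouting)


def test_dpt_outside_grid_rejected(scene, sprouts):
    with pytest.raises(DomainError):
        simulate_perfusion_truth(scene, sprouts, 5.0)


def test_unreachable_compartments_censored(scene):
    params = {"p_prox_anastomosis": {4.0: 0.0, 8.0: 0.0},
              "p_dist_anastomosis": {4.0: 0.0, 8.0: 0.0}}
    t = simulate_perfusion_truth(scene, [], 4.0, params=params, seed=0)
    assert not is_censored(t.arrival("A"))
    for roi in "BCD":
        assert is_censored(t.arrival(roi))


def test_proximal_anastomosis_rate_brute_force(scene, sprouts):
    rng = np.random.default_rng(1)
    hits = sum(simulate_perfusion_truth(scene, sprouts, 4.0, seed=rng).anastomosis_proximal
               for _ in range(10_000))
    assert abs(hits / 10_000 - 0.9) < 0.01


def test_wound_connected_probability_rises_to_one(scene):
    rng = np.random.default_rng(2)
    by_dpt = {}
    for dpt in (4.0, 6.0, 8.0):
        conn = 0
        for _ in range(400):
            sp = assign_perfusion(
                simulate_sprouting(scene, [4.0, 6.0, 8.0], seed=rng), seed=rng)
            conn += simulate_perfusion_truth(scene, sp, dpt, seed=rng).wound_connected
        by_dpt[dpt] = conn / 400
    assert by_dpt[4.0] < 0.2          # no functional crossing yet
    assert by_dpt[6.0] > by_dpt[4.0]  # develops between 5 and 8 dpt
    assert by_dpt[8.0] > 0.9          # essentially all connected


def test_retrograde_distal_fill_sign(scene, sprouts):
    rng = np.random.default_rng(3)
    for _ in range(200):
        t = simulate_perfusion_truth(scene, sprouts, 4.0, seed=rng)
        if t.anastomosis_distal and not is_censored(t.arrival("C")):
            assert t.flow_direction_distal == "retrograde"
            assert t.arrival("D") < t.arrival("C")  # dt_DC < 0


def test_removing_anastomosis_never_makes_arrival_earlier(scene, sprouts):
    """Path consistency: cutting the distal vein link delays or censors C/D."""
    on = {"p_dist_anastomosis": {4.0: 1.0, 8.0: 1.0}}
    off = {"p_dist_anastomosis": {4.0: 0.0, 8.0: 0.0}}
    for seed in range(100):
        t1 = simulate_perfusion_truth(scene, sprouts, 4.0, params=on, seed=seed)
        t0 = simulate_perfusion_truth(scene, sprouts, 4.0, params=off, seed=seed)
        for roi in "CD":
            if is_censored(t0.arrival(roi)):
                continue
            assert t0.arrival(roi) >= t1.arrival(roi) - 1e-9


def test_dt_cb_zero_at_8dpt(scene, sprouts):
    rng = np.random.default_rng(4)
    for _ in range(50):
        t = simulate_perfusion_truth(scene, sprouts, 8.0, seed=rng)
        if not is_censored(t.arrival("C")) and not is_censored(t.arrival("B")):
            assert t.arrival("C") == pytest.approx(t.arrival("B"))
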