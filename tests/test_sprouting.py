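import numpy as np
import pytest
from hypothesis import given, strategies as st

from earwound.config import ConfigError
from earwound.sim import (CONTROL, TreatmentSpec, assign_perfusion,
                          simulate_sprouting)

SESSIONS = [3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5]


def _counts_at(scene, t, n_rep, rng, treatment=CONTROL):
    out = np.empty(n_rep)
    for i in range(n_rep):
        sp = simulate_sprouting(scene, SESSIONS, treatment=treatment, seed=rng)
        out[i] = sum(1 for s in sp if s.birth_dpt <= t)
    return out


def test_cumulative_count_is_poisson_with_linear_mean(scene):
    """Monte-Carlo mean and variance match rate * (t - onset) within 3 SE."""
    rng = np.random.default_rng(0)
    n = 10_000
    counts = _counts_at(scene, 6.5, n, rng)
    expected = 1.5 * (6.5 - 3.5)
    se_mean = np.sqrt(expected / n)
    assert abs(counts.mean() - expected) < 3 * se_mean
    # Poisson: variance equals the mean; SE of the variance ~ sqrt(2/n)*var
    assert abs(counts.var() - expected) < 3 * np.sqrt(2 / n) * expected * 1.5


def test_zero_birth_factor_gives_no_sprouts(scene):
    t = TreatmentSpec(group="combo", birth_rate_factor=0.0)
    sp = simulate_sprouting(scene, SESSIONS, treatment=t, seed=1)
    assert sp == []


def test_sprouting_is_distal_only(scene):
    rng = np.random.default_rng(2)
    for _ in range(50):
        for s in simulate_sprouting(scene, SESSIONS, seed=rng):
            assert s.side == "distal"
            assert s.parent_stump in {v.vessel_id for v in scene.distal_stumps}


@given(birth=st.floats(3.5, 6.5), t1=st.floats(3.0, 9.0), t2=st.floats(3.0, 9.0))
def test_length_is_zero_before_birth_and_nondecreasing(scene, birth, t1, t2):
    sp = simulate_sprouting(scene, SESSIONS, seed=3)
    for s in sp[:3]:
        assert s.length_at(s.birth_dpt - 0.1) == 0.0
        lo, hi = sorted([t1, t2])
        assert s.length_at(lo) <= s.length_at(hi)


def test_negative_rate_rejected(scene):
    with pytest.raises(ConfigError):
        simulate_sprouting(scene, SESSIONS, birth_rate=-1.0)
    with pytest.raises(ConfigError):
        simulate_sprouting(scene, [4.0, 3.5], birth_rate=1.0)


def test_perfusion_flags_all_set_at_p_one(scene):
    sp = simulate_sprouting(scene, SESSIONS, seed=4)
    assert all(s.is_perfused for s in assign_perfusion(sp, 1.0, seed=0))
    assert not any(s.is_perfused for s in assign_perfusion(sp, 0.0, seed=0))


def test_perfused_fraction_binomial(scene):
    """3e4 sprouts at p = 2/3 land within the binomial band 0.667 +- 0.006."""
    rng = np.random.default_rng(5)
    flags = []
    while len(flags) < 30_000:
        sp = simulate_sprouting(scene, [3.5, 20.0], seed=rng)
        flags.extend(s.is_perfused for s in assign_perfusion(sp, 2 / 3, seed=rng))
    frac = np.mean(flags[:30_000])
    assert abs(frac - 2 / 3) < 0.006


def test_invalid_p_perfused_rejected(scene):
    sp = simulate_sprouting(scene, SESSIONS, seed=6)
    with pytest.raises(ConfigError):
        assign_perfusion(sp, 1.5)


def test_treatment_factor_ordering():
    mono = TreatmentSpec.for_group("sunitinib")
    combo = TreatmentSpec.for_group("combo")
    ctrl = TreatmentSpec.for_group("control")
    assert ctrl.birth_rate_factor == ctrl.elongation_factor == 1.0
    assert combo.birth_rate_factor <= mono.birth_rate_factor <= 1.0
    assert combo.elongation_factor <= mono.elongation_factor <= 1.0


def test_treatment_suppresses_birth_mean(scene):
    rng = np.random.default_rng(7)
    combo = TreatmentSpec.for_group("combo")
    ctrl = _counts_at(scene, 6.5, 2000, rng).mean()
    trt = _counts_at(scene, 6.5, 2000, rng, treatment=combo).mean()
    assert trt < 0.5 * ctrl  # factor 0.25 with Monte-Carlo slack
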