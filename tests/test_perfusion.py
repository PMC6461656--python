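import numpy as np
import pytest
from hypothesis import given, strategies as st

from earwound.perfusion import (classify_anastomosis, compute_metrics,
                                count_perfused_sprouts, detect_arrival,
                                is_censored)

PERIOD = 2 / 3


def _step_trace(jump_at=40, lo=100.0, hi=200.0, n=100):
    tr = np.full(n, lo)
    tr[:30:2] += 1.0
    tr[1:30:2] -= 1.0  # baseline SD ~ 1
    tr[jump_at:] = hi
    return tr


def test_step_arrival_interpolated():
    t = detect_arrival(_step_trace(), frame_period_s=PERIOD)
    assert abs(t - 26.3) < PERIOD  # crossing at frame ~39-39.5


def test_flat_trace_censored():
    assert is_censored(detect_arrival(np.full(100, 50.0), frame_period_s=PERIOD))


def test_single_frame_spike_not_an_arrival():
    tr = _step_trace(jump_at=50)
    tr[50:] = 100.0
    tr[50] = 500.0  # isolated spike
    assert is_censored(detect_arrival(tr, frame_period_s=PERIOD,
                                      min_consecutive=2))


def test_zero_baseline_sd_uses_floor():
    tr = np.full(100, 10.0)
    tr[60:] = 11.0  # tiny but sustained rise over a perfectly flat baseline
    t = detect_arrival(tr, frame_period_s=PERIOD)
    assert t == pytest.approx(59 * PERIOD, abs=PERIOD)


def test_trace_shorter_than_baseline_rejected():
    with pytest.raises(ValueError):
        detect_arrival(np.ones(20), n_baseline=30)


@given(k1=st.floats(1.0, 4.0), k2=st.floats(4.0, 8.0))
def test_raising_threshold_never_makes_arrival_earlier(k1, k2):
    rng = np.random.default_rng(11)
    tr = 100 + rng.normal(0, 2, 150)
    tr[70:] += np.linspace(0, 80, 80)
    t1 = detect_arrival(tr, frame_period_s=PERIOD, k_sd=k1)
    t2 = detect_arrival(tr, frame_period_s=PERIOD, k_sd=k2)
    if not is_censored(t2):
        assert not is_censored(t1)
        assert t1 <= t2 + 1e-9


def test_metrics_worked_example():
    res = compute_metrics({"A": 10.0, "B": 10.5, "C": 12.0, "D": 11.0})
    assert res.dt_ba == pytest.approx(0.5)
    assert res.dt_cb == pytest.approx(1.5)
    assert res.dt_dc == pytest.approx(-1.0)
    assert res.integral_dt == pytest.approx(3.0)
    assert all(res.perfused.values())
    assert res.anastomosis == {"proximal": True, "distal": True}


def test_censored_propagation():
    res = compute_metrics({"A": 10.0, "B": 10.5, "C": float("nan"),
                           "D": float("nan")})
    assert is_censored(res.dt_cb) and is_censored(res.dt_dc)
    assert is_censored(res.integral_dt)
    assert res.perfused == {"proximal": True, "wound": False, "distal": False}


def test_anastomosis_rule_boundaries():
    mk = lambda ba, dc: compute_metrics(
        {"A": 10.0, "B": 10.0 + ba, "C": 20.0, "D": 20.0 + dc})
    assert classify_anastomosis(mk(0.5, 5.0)) == {"proximal": True, "distal": False}
    # retrograde but fast distal fill still indicates a vein connection
    assert classify_anastomosis(mk(5.0, -1.0)) == {"proximal": False, "distal": True}
    # strict inequality at exactly 1.3 s
    assert classify_anastomosis(mk(1.3, -1.3)) == {"proximal": False, "distal": False}


def test_integral_invariant_under_time_shift():
    base = {"A": 10.0, "B": 11.0, "C": 14.0, "D": 12.5}
    r0 = compute_metrics(base)
    for shift in (-5.0, 3.3, 40.0):
        r = compute_metrics({k: v + shift for k, v in base.items()})
        assert r.integral_dt == pytest.approx(r0.integral_dt)


def test_count_perfused_sprouts_rules():
    img = np.zeros((60, 60))
    skels = []
    # perfused sprout: bright along its whole path
    p1 = np.array([[10, c] for c in range(10, 30)])
    img[10, 10:30] = 100.0
    skels.append(p1)
    # unperfused: stays at baseline
    skels.append(np.array([[20, c] for c in range(10, 30)]))
    # exactly half covered (after the 4-px root skip): closed boundary
    p3 = np.array([[30, c] for c in range(10, 30)])
    img[30, 14:22] = 100.0  # 8 of 16 counted pixels
    skels.append(p3)
    n_perf, n_tot = count_perfused_sprouts(skels, img, baseline_stats=(0.0, 1.0))
    assert (n_perf, n_tot) == (2, 3)

    assert count_perfused_sprouts([], img) == (0, 0)
    n_perf, n_tot = count_perfused_sprouts(skels, np.zeros((60, 60)),
                                           baseline_stats=(0.0, 1.0))
    assert (n_perf, n_tot) == (0, 3)
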