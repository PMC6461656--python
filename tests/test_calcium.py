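import numpy as np
import pytest

from earwound.calcium import compute_dff, detect_transients
from earwound.sim import render_region_trace, simulate_calcium_events

PERIOD = 0.66


def _trace_with_events(times, amp=1.0, tau=5.0, n=2000, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) * PERIOD
    dff = np.zeros(n)
    for t0 in times:
        m = t >= t0
        dff[m] += amp * np.exp(-(t[m] - t0) / tau)
    if noise_sd:
        dff += rng.normal(0, noise_sd, n)
    return 100.0 * (1.0 + dff)


def test_constant_trace_gives_zero_dff():
    dff = compute_dff(np.full(500, 123.0), frame_period_s=PERIOD)
    assert np.allclose(dff, 0.0)


def test_plateau_dff_value():
    f = np.full(1000, 100.0)
    f[500:520] = 150.0
    dff = compute_dff(f, frame_period_s=PERIOD)
    assert dff[505:515].max() == pytest.approx(0.5, abs=1e-6)


def test_slow_drift_removed():
    f = 100.0 + np.linspace(0, 5, 2000)  # slow linear drift, no events
    dff = compute_dff(f, frame_period_s=PERIOD)
    assert np.abs(dff).max() < 0.05


def test_all_zero_trace_rejected():
    with pytest.raises(ValueError):
        compute_dff(np.zeros(500))


def test_noise_free_events_recovered():
    times = [100.0, 300.0, 550.0, 800.0, 1100.0]
    f = _trace_with_events(times, noise_sd=0.0)
    dff = compute_dff(f, frame_period_s=PERIOD)
    events = detect_transients(dff, frame_period_s=PERIOD)
    assert len(events) == 5
    for ev, t0 in zip(events, times):
        assert abs(ev.onset_s - t0) <= 1.0


def test_short_event_rejected():
    # a 1 s box above threshold fails the 2 s duration filter
    f = np.full(1000, 100.0)
    f[500] = 300.0
    dff = compute_dff(f, frame_period_s=PERIOD)
    assert detect_transients(dff, frame_period_s=PERIOD) == []


def test_flat_noise_rarely_triggers():
    """False positives under pure noise stay below 1% of sessions."""
    rng = np.random.default_rng(42)
    fp = 0
    for _ in range(200):
        f = 100.0 * (1.0 + rng.normal(0, 0.05, 2000))
        dff = compute_dff(f, frame_period_s=PERIOD)
        fp += bool(detect_transients(dff, frame_period_s=PERIOD))
    assert fp <= 2


def test_counts_monotone_in_thresholds():
    f = _trace_with_events([100, 200, 400, 700, 900, 1200], amp=0.8,
                           noise_sd=0.05, seed=1)
    dff = compute_dff(f, frame_period_s=PERIOD)
    by_k = [len(detect_transients(dff, frame_period_s=PERIOD, k_sd=k))
            for k in (2.0, 3.0, 5.0, 8.0)]
    assert by_k == sorted(by_k, reverse=True)
    by_dur = [len(detect_transients(dff, frame_period_s=PERIOD, min_duration_s=d))
              for d in (1.0, 2.0, 5.0, 15.0)]
    assert by_dur == sorted(by_dur, reverse=True)


def test_recall_and_false_positives_over_sessions():
    """Amplitude >= 5x noise SD: recall >= 0.95, FP <= 0.05 per session."""
    rng = np.random.default_rng(7)
    n_true = n_det = 0
    fp_sessions = 0
    for _ in range(200):
        train = simulate_calcium_events(5.0, "distal", seed=rng)
        df = render_region_trace(train, seed=rng)
        dff = compute_dff(df["f"].to_numpy(), frame_period_s=PERIOD)
        events = detect_transients(dff, frame_period_s=PERIOD)
        # events separated by more than the merge window are resolvable
        times = train.event_times_s
        resolvable = 1 + int(np.sum(np.diff(times) > 15.0)) if len(times) else 0
        n_true += resolvable
        n_det += min(len(events), resolvable)
        fp_sessions += max(0, len(events) - len(times))
    assert n_det / max(n_true, 1) >= 0.95
    assert fp_sessions / 200 <= 0.05
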