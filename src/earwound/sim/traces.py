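"""Trace-level rendering: ROI intensity time series from ground truth.

This is the fast counterpart to full image rendering: it produces, for
each ROI (tracer channel) or region (GCaMP channel), the mean-intensity
time series that trace extraction from a rendered image stack would
yield, with the same acquisition timing and comparable noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import DEFAULTS
from .calcium_truth import CalciumEventTrain
from .perfusion_truth import PerfusionGroundTruth, is_censored


def tracer_fill(t_s: np.ndarray, arrival_s: float, amplitude: float,
                tau_s: float) -> np.ndarray:
    """Exponential-saturation fill profile starting at the arrival time."""
    out = np.zeros_like(t_s, dtype=float)
    if is_censored(arrival_s):
        return out
    dt = t_s - arrival_s
    m = dt > 0
    out[m] = amplitude * (1.0 - np.exp(-dt[m] / tau_s))
    return out


def render_roi_traces(
    truth: PerfusionGroundTruth,
    params: dict | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    noise: bool = True,
) -> pd.DataFrame:
    """Tracer (red channel) traces for ROIs A-D of one perfusion session.

    Returns a frame-indexed DataFrame with columns ``time_s`` and
    ``roi_A`` .. ``roi_D``.  The noise SD is ``trace_amplitude /
    trace_snr`` (default SNR 10).
    """
    p = dict(DEFAULTS["imaging"])
    if params:
        p.update(params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(truth.n_frames)
    t = np.arange(n) * p["frame_period_s"]
    base, amp = p["trace_baseline"], p["trace_amplitude"]
    sd = amp / p["trace_snr"] if noise else 0.0
    data = {"time_s": t}
    for roi in "ABCD":
        y = base + tracer_fill(t, truth.arrival(roi), amp, p["tracer_fill_tau_s"])
        if noise:
            y = y + rng.normal(0.0, sd, size=n)
        data[f"roi_{roi}"] = y
    return pd.DataFrame(data)


def render_region_trace(
    train: CalciumEventTrain,
    params: dict | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    noise: bool = True,
) -> pd.DataFrame:
    """GCaMP (green channel) mean-intensity trace for one region/session.

    Baseline fluorescence F0 with each transient adding
    ``F0 * amplitude * exp(-(t - t_event)/tau)``; multiplicative Gaussian
    noise on the dF/F scale.
    """
    p = dict(DEFAULTS["calcium"])
    if params:
        p.update(params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    period = p["frame_period_s"]
    n = int(round(train.session_s / period))
    t = np.arange(n) * period
    f0 = 100.0
    dff = np.zeros(n)
    for t0, a in zip(train.event_times_s, train.amplitudes_dff):
        m = t >= t0
        dff[m] += a * np.exp(-(t[m] - t0) / train.decay_tau_s)
    if noise:
        dff = dff + rng.normal(0.0, p["noise_dff_sd"], size=n)
    return pd.DataFrame({"time_s": t, "f": f0 * (1.0 + dff)})
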