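"""Tracer arrival-time estimation and perfusion readouts.

The tracer bolus reaches ROI *i* at time t(i); perfusion of a vascular
compartment is summarized by the pairwise differences
dt_{j-i} = t(j) - t(i) for (i, j) = (A, B), (B, C), (C, D) and by the
integral flow measure |dt_BA| + |dt_CB| + |dt_DC|.  An anastomosis
between a stump and an adjacent vein is inferred from |dt| < 1.3 s
(about two frame periods) along that stump; a compartment counts as
perfused when its dt is defined and below the 66.66 s window (the
100-frame minimum recording).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS
from .sim.perfusion_truth import CENSORED, is_censored

__all__ = ["ArrivalResult", "CENSORED", "is_censored", "detect_arrival",
           "compute_metrics", "classify_anastomosis", "count_perfused_sprouts"]


@dataclass
class ArrivalResult:
    """Per-session arrival times and derived perfusion metrics.

    ``dt_*`` fields are NaN iff either endpoint is censored;
    ``integral_dt`` is present iff all three dt values are.
    """

    t: dict = field(default_factory=dict)  # {A,B,C,D} -> seconds or NaN
    dt_ba: float = CENSORED
    dt_cb: float = CENSORED
    dt_dc: float = CENSORED
    integral_dt: float = CENSORED
    perfused: dict = field(default_factory=dict)  # proximal/wound/distal -> bool
    anastomosis: dict = field(default_factory=dict)  # proximal/distal -> bool
    recording_window_s: float = 66.66


def detect_arrival(
    trace: np.ndarray,
    frame_period_s: float = DEFAULTS["imaging"]["frame_period_s"],
    n_baseline: int = DEFAULTS["imaging"]["n_baseline_frames"],
    k_sd: float = DEFAULTS["detection"]["k_sd"],
    min_consecutive: int = DEFAULTS["detection"]["min_consecutive"],
    sd_floor: float = 1e-9,
) -> float:
    """Arrival time (s from recording start) of a sustained intensity rise.

    The baseline mean m and SD s are taken over the first ``n_baseline``
    frames; the arrival frame is the first frame after the baseline at
    which the trace stays at or above m + k_sd * s for
    ``min_consecutive`` consecutive frames.  The arrival time is then
    refined to sub-frame precision by linearly interpolating the
    crossing of the half-rise level (midway between the baseline and
    the post-arrival plateau): unlike the k_sd level, the half-rise
    level does not scale with the noise, so the refined time is stable
    across signal-to-noise ratios.  Returns ``CENSORED`` (NaN) if no
    sustained crossing occurs within the recording.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if len(trace) <= n_baseline:
        raise ValueError(
            f"trace length {len(trace)} not larger than baseline {n_baseline}")
    base = trace[:n_baseline]
    m = float(base.mean())
    s = float(base.std(ddof=1))
    if s == 0.0:
        s = sd_floor
    thr = m + k_sd * s

    above = trace >= thr
    n = len(trace)
    run = 0
    for f in range(n_baseline, n):
        run = run + 1 if above[f] else 0
        if run >= min_consecutive:
            f0 = f - min_consecutive + 1  # first frame of the sustained run
            plateau = float(np.median(trace[f0:min(f0 + 10, n)]))
            level = (m + plateau) / 2.0
            if plateau <= thr:
                level = thr  # weak rise: fall back to the detection level
            g = f0 - 1
            while g < n - 1 and trace[g] < level:
                g += 1
            prev, cur = trace[g - 1], trace[g]
            if cur > prev:
                frac = float(np.clip((level - prev) / (cur - prev), 0.0, 1.0))
            else:
                frac = 0.0
            return float((g - 1 + frac) * frame_period_s)
    return CENSORED


def compute_metrics(
    arrivals: dict,
    recording_window_s: float = DEFAULTS["detection"]["perfusion_window_s"],
    anastomosis_threshold_s: float = DEFAULTS["detection"]["anastomosis_threshold_s"],
) -> ArrivalResult:
    """Derive dt pairs, the integral flow measure and the boolean readouts.

    Signs are preserved: a negative dt_DC indicates retrograde flow in
    the distal stump (tracer entering from the distal end).
    """
    t = {roi: float(arrivals.get(roi, CENSORED)) for roi in "ABCD"}

    def diff(j, i):
        if is_censored(t[j]) or is_censored(t[i]):
            return CENSORED
        return t[j] - t[i]

    dt_ba = diff("B", "A")
    dt_cb = diff("C", "B")
    dt_dc = diff("D", "C")
    dts = (dt_ba, dt_cb, dt_dc)
    integral = (abs(dt_ba) + abs(dt_cb) + abs(dt_dc)
                if not any(is_censored(d) for d in dts) else CENSORED)

    def perfused(d):
        return (not is_censored(d)) and abs(d) < recording_window_s

    res = ArrivalResult(
        t=t, dt_ba=dt_ba, dt_cb=dt_cb, dt_dc=dt_dc, integral_dt=integral,
        perfused={"proximal": perfused(dt_ba), "wound": perfused(dt_cb),
                  "distal": perfused(dt_dc)},
        recording_window_s=recording_window_s,
    )
    res.anastomosis = classify_anastomosis(res, anastomosis_threshold_s)
    return res


def classify_anastomosis(
    result: ArrivalResult,
    threshold_s: float = DEFAULTS["detection"]["anastomosis_threshold_s"],
) -> dict:
    """Anastomosis per side from the |dt| < threshold rule (strict).

    Absolute values are used: a fast retrograde distal fill (negative
    dt_DC) also indicates a vein connection.
    """
    def near_zero(d):
        return (not is_censored(d)) and abs(d) < threshold_s

    return {"proximal": near_zero(result.dt_ba), "distal": near_zero(result.dt_dc)}


def count_perfused_sprouts(
    sprout_skeletons: list[np.ndarray],
    red_projection: np.ndarray,
    snr_threshold: float = DEFAULTS["detection"]["snr_threshold"],
    coverage_fraction: float = DEFAULTS["detection"]["coverage_fraction"],
    baseline_stats: tuple[float, float] | None = None,
    skip_start_px: int = 4,
) -> tuple[int, int]:
    """Count sprouts whose skeleton colocalizes with tracer signal.

    ``sprout_skeletons`` is a list of (N, 2) integer (row, col) pixel
    paths in the frame of ``red_projection`` (a z-compressed red-channel
    image), ordered wall to tip.  A sprout is perfused iff at least
    ``coverage_fraction`` (closed boundary) of its skeleton pixels
    exceed the red baseline mean + ``snr_threshold`` * SD.  The first
    ``skip_start_px`` pixels of each path are excluded: they abut the
    parent trunk, whose own tracer signal would otherwise be attributed
    to the sprout.  The baseline is estimated robustly from the image
    (median and scaled MAD) unless given explicitly.
    """
    n_total = len(sprout_skeletons)
    if n_total == 0:
        return 0, 0
    img = np.asarray(red_projection, dtype=float)
    if baseline_stats is None:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        sd = 1.4826 * mad
        if sd == 0.0:
            sd = float(img.std()) or 1e-9
        baseline_stats = (med, sd)
    m, s = baseline_stats
    thr = m + snr_threshold * s

    n_perf = 0
    for path in sprout_skeletons:
        px = np.asarray(path, dtype=int)
        if px.size == 0:
            warnings.warn("empty sprout skeleton; counted as not perfused")
            continue
        skip = min(skip_start_px, max(0, len(px) - 3))
        if skip:
            px = px[skip:]
        rr = np.clip(px[:, 0], 0, img.shape[0] - 1)
        cc = np.clip(px[:, 1], 0, img.shape[1] - 1)
        frac = float(np.mean(img[rr, cc] > thr))
        if frac >= coverage_fraction:
            n_perf += 1
    return n_perf, n_total
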