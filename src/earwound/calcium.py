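"""dF/F normalization and Ca2+ transient detection.

A minimal, parameterized transient detector for GCaMP region traces:
running-percentile baseline F0, robust (MAD-based) thresholding of the
dF/F series, and a duration filter.  Counts per 22-minute session and
region (proximal vs distal stump/sprouts) feed the side-asymmetry
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks

from .config import DEFAULTS

__all__ = ["TransientEvent", "compute_dff", "detect_transients", "count_by_side"]


@dataclass(frozen=True)
class TransientEvent:
    onset_s: float
    peak_s: float
    peak_dff: float
    duration_s: float
    region: str = ""


def compute_dff(
    trace: np.ndarray,
    frame_period_s: float = DEFAULTS["calcium"]["frame_period_s"],
    baseline_percentile: float = DEFAULTS["detection"]["ca_baseline_percentile"],
    window_s: float = DEFAULTS["detection"]["ca_baseline_window_s"],
    f0_floor: float = 1e-6,
) -> np.ndarray:
    """dF/F with a running-percentile baseline.

    F0 is the ``baseline_percentile`` (default 20th) percentile of the
    raw trace over a sliding window (default 60 s), which tracks slow
    drift while ignoring transients; F0 is floored to avoid division
    blow-up.
    """
    f = np.asarray(trace, dtype=float)
    if f.ndim != 1 or len(f) < 100:
        raise ValueError("trace must be 1-D with at least 100 frames")
    if np.all(f == 0):
        raise ValueError("all-zero trace: no baseline fluorescence")
    w = max(3, int(round(window_s / frame_period_s)) | 1)
    f0 = percentile_filter(f, baseline_percentile, size=w, mode="nearest")
    f0 = np.maximum(f0, f0_floor)
    return (f - f0) / f0


def detect_transients(
    dff: np.ndarray,
    frame_period_s: float = DEFAULTS["calcium"]["frame_period_s"],
    k_sd: float = DEFAULTS["detection"]["ca_k_sd"],
    min_duration_s: float = DEFAULTS["detection"]["ca_min_duration_s"],
    merge_gap_s: float = DEFAULTS["detection"]["ca_merge_gap_s"],
    region: str = "",
) -> list[TransientEvent]:
    """Maximal supra-threshold runs of the dF/F series as events.

    The threshold is ``k_sd`` robust SDs (1.4826 * MAD) above the median
    of the series; runs separated by gaps shorter than ``merge_gap_s``
    are merged, and events shorter than ``min_duration_s`` are dropped.
    A run containing several peaks is split where the trough between
    two peaks falls below half the smaller peak, so that overlapping
    transients (a second onset arriving before the first has decayed)
    are counted separately.
    """
    x = np.asarray(dff, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    sd = 1.4826 * mad
    if sd == 0.0:
        sd = float(x.std()) or 1e-9
    thr = med + k_sd * sd

    above = x > thr
    if not above.any():
        return []
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    ends = list(np.flatnonzero(~above[1:] & above[:-1]) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))

    # merge runs separated by short sub-threshold gaps
    gap_frames = merge_gap_s / frame_period_s
    merged: list[list[int]] = []
    for s0, e0 in zip(starts, ends):
        if merged and s0 - merged[-1][1] < gap_frames:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])

    events = []
    for s0, e0 in merged:
        for a, b in _split_overlapping(x, s0, e0, thr):
            dur = (b - a) * frame_period_s
            if dur < min_duration_s:
                continue
            seg = x[a:b]
            pk = int(np.argmax(seg))
            events.append(TransientEvent(
                onset_s=a * frame_period_s,
                peak_s=(a + pk) * frame_period_s,
                peak_dff=float(seg[pk]),
                duration_s=float(dur),
                region=region,
            ))
    return events


def _split_overlapping(x: np.ndarray, s0: int, e0: int, thr: float):
    """Split a supra-threshold run at deep inter-peak troughs."""
    seg = x[s0:e0]
    peaks, _ = find_peaks(seg, height=thr)
    if len(peaks) < 2:
        return [(s0, e0)]
    bounds = [s0]
    for p1, p2 in zip(peaks[:-1], peaks[1:]):
        rel = p1 + int(np.argmin(seg[p1:p2 + 1]))
        if seg[rel] <= 0.5 * min(seg[p1], seg[p2]):
            bounds.append(s0 + rel)
    bounds.append(e0)
    return list(zip(bounds[:-1], bounds[1:]))


def count_by_side(
    events_by_session: dict[tuple[str, float, str], list[TransientEvent]],
) -> pd.DataFrame:
    """Tidy per-(animal, session, region) transient counts.

    ``events_by_session`` maps (animal_id, dpt, region) to the detected
    events of that session.
    """
    rows = [
        {"animal_id": aid, "dpt": float(dpt), "region": region,
         "ca_count": len(evts)}
        for (aid, dpt, region), evts in sorted(events_by_session.items())
    ]
    return pd.DataFrame(rows, columns=["animal_id", "dpt", "region", "ca_count"])
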