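"""Ground-truth endothelial Ca2+ transient trains.

Transients are modelled as a Poisson process that is homogeneous within
a 22-minute session but whose session rate follows a triangular ramp
over the healing time course: rising from 3 dpt, peaking at 5 dpt with a
mean of 5 events per distal session, and falling back to baseline by
8 dpt.  Activity is strongly asymmetric: the proximal rate is a small
fraction (default 0.1) of the distal rate, mirroring the observation
that clear transients occur almost exclusively on the distal stump and
its sprouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import DEFAULTS


@dataclass
class CalciumEventTrain:
    """Event times (s within the session) plus kinetic parameters."""

    dpt: float
    region: str  # "proximal" | "distal"
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitudes_dff: np.ndarray = field(default_factory=lambda: np.array([]))
    decay_tau_s: float = 5.0
    session_s: float = 1320.0

    @property
    def count(self) -> int:
        return int(len(self.event_times_s))


def session_rate(dpt: float, region: str = "distal", params: dict | None = None) -> float:
    """Expected transients per session at ``dpt`` under the default ramp."""
    p = dict(DEFAULTS["calcium"])
    if params:
        p.update(params)
    peak_t, peak_r = p["peak_dpt"], p["peak_rate_per_session"]
    rise, fall = p["rise_start_dpt"], p["fall_end_dpt"]
    if dpt <= rise or dpt >= fall:
        rate = 0.0
    elif dpt <= peak_t:
        rate = peak_r * (dpt - rise) / (peak_t - rise)
    else:
        rate = peak_r * (fall - dpt) / (fall - peak_t)
    if region == "proximal":
        rate *= p["proximal_factor"]
    elif region != "distal":
        raise ValueError(f"unknown region {region!r}")
    return float(rate)


def simulate_calcium_events(
    dpt: float,
    region: str,
    params: dict | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> CalciumEventTrain:
    """Draw one session's transient train (sorted times in [0, 1320 s])."""
    p = dict(DEFAULTS["calcium"])
    if params:
        p.update(params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean = session_rate(dpt, region, p)
    n = rng.poisson(mean)
    times = np.sort(rng.uniform(0.0, p["session_s"], size=n))
    cv = p["amplitude_dff_cv"]
    sigma2 = np.log1p(cv**2)
    mu = np.log(p["amplitude_dff_mean"]) - sigma2 / 2.0
    amps = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return CalciumEventTrain(
        dpt=float(dpt), region=region,
        event_times_s=times, amplitudes_dff=amps,
        decay_tau_s=p["decay_tau_s"], session_s=p["session_s"],
    )
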