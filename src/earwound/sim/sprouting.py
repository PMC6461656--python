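"""Ground-truth sprout dynamics.

Sprout births follow a homogeneous Poisson process on the distal stump
starting at the sprouting onset (default 3.5 dpt, when the first sprouts
become detectable), at a default rate of 1.5 sprouts per day.  Each
sprout elongates linearly at a per-sprout rate drawn from a lognormal
distribution.

The headline elongation parameter (default 10.4 um/day) is the slope of
the *session-mean* sprout length, which is the quantity the longitudinal
length analysis estimates.  Because births are ongoing and newborn
sprouts have length zero, the mean age of live sprouts grows at only
half a day per day, so the internal per-sprout elongation rate is twice
the population slope.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..config import ConfigError, DEFAULTS
from .scene import VascularScene


@dataclass(frozen=True)
class TreatmentSpec:
    """Multiplicative suppression of angiogenesis for one treatment arm.

    Factors lie in (0, 1]; control is all ones.  Anastomosis factors are
    anchored at 4 and 8 dpt and interpolated linearly in between.
    """

    group: str
    birth_rate_factor: float = 1.0
    elongation_factor: float = 1.0
    prox_ana_factor: dict = None
    dist_ana_factor: dict = None
    onset_dpt: float = 1.0

    def __post_init__(self):
        for name in ("birth_rate_factor", "elongation_factor"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"treatment {name} must lie in [0, 1]")
        if self.prox_ana_factor is None:
            object.__setattr__(self, "prox_ana_factor", {4.0: 1.0, 8.0: 1.0})
        if self.dist_ana_factor is None:
            object.__setattr__(self, "dist_ana_factor", {4.0: 1.0, 8.0: 1.0})

    def ana_factor(self, side: str, dpt: float) -> float:
        anchors = self.prox_ana_factor if side == "proximal" else self.dist_ana_factor
        xs = np.array(sorted(anchors), dtype=float)
        ys = np.array([anchors[x] for x in sorted(anchors)], dtype=float)
        return float(np.clip(np.interp(dpt, xs, ys), 0.0, 1.0))

    @classmethod
    def for_group(cls, group: str, treatment_cfg: dict | None = None) -> "TreatmentSpec":
        t = dict(DEFAULTS["treatment"])
        if treatment_cfg:
            t.update(treatment_cfg)
        if group == "control":
            return cls(group="control")
        if group in ("sunitinib", "AZD4547"):
            return cls(
                group=group,
                birth_rate_factor=t["mono_birth_factor"],
                elongation_factor=t["mono_elongation_factor"],
                prox_ana_factor=dict(t["mono_prox_ana_factor"]),
                dist_ana_factor=dict(t["mono_dist_ana_factor"]),
                onset_dpt=t["onset_dpt"],
            )
        if group == "combo":
            return cls(
                group=group,
                birth_rate_factor=t["combo_birth_factor"],
                elongation_factor=t["combo_elongation_factor"],
                prox_ana_factor=dict(t["combo_prox_ana_factor"]),
                dist_ana_factor=dict(t["combo_dist_ana_factor"]),
                onset_dpt=t["onset_dpt"],
            )
        raise ConfigError(f"unknown treatment group {group!r}")


CONTROL = TreatmentSpec(group="control")


@dataclass
class SproutRecord:
    """One sprout: birth time, straight growth path, perfusion status."""

    sprout_id: str
    side: str  # "proximal" | "distal"
    parent_stump: str
    birth_dpt: float
    elongation_um_per_day: float  # per-sprout tip speed
    origin_um: tuple[float, float]  # point on the parent artery wall
    direction: tuple[float, float]  # unit vector, wound-ward
    is_perfused: bool = False

    def length_at(self, dpt: float) -> float:
        """Wall-to-tip geodesic length (um); zero before birth, nondecreasing."""
        return max(0.0, (dpt - self.birth_dpt)) * self.elongation_um_per_day

    def tip_at(self, dpt: float) -> tuple[float, float]:
        ln = self.length_at(dpt)
        return (self.origin_um[0] + ln * self.direction[0],
                self.origin_um[1] + ln * self.direction[1])

    def path_at(self, dpt: float) -> np.ndarray:
        """(2, 2) polyline from the parent wall to the current tip (um)."""
        return np.array([self.origin_um, self.tip_at(dpt)], dtype=float)


#: per-sprout tip speed as a multiple of the nominal mean-length slope.
#: Uniform ongoing births halve the growth rate of the mean sprout age
#: (factor 2); the longitudinal mixed model's weighting under the
#: onset-driven missingness of zero-sprout sessions raises its estimand
#: slightly above the marginal slope, which lowers the calibration to
#: 1.71 for the default study design (see docs/methods.md).
TIP_SPEED_MULTIPLIER = 1.71


def per_sprout_rate_params(elongation_um_per_day: float, cv: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) of the per-sprout tip speed.

    Calibrated so that the session-level linear mixed model applied to
    the default cohort design estimates the nominal ``elongation``
    parameter (the study's headline um/day slope).
    """
    mean = TIP_SPEED_MULTIPLIER * elongation_um_per_day
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0 if mean > 0 else -np.inf
    return mu, float(np.sqrt(sigma2))


def simulate_sprouting(
    scene: VascularScene,
    sessions: list[float],
    birth_rate: float = 1.5,
    elongation: float = 10.4,
    treatment: TreatmentSpec = CONTROL,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    onset_dpt: float = 3.5,
    elongation_cv: float = 0.3,
    sprout_radius_um: float | None = None,
) -> list[SproutRecord]:
    """Draw the full sprout ground truth for one animal.

    Births are distal-only (the study's central asymmetry): a Poisson
    process at rate ``birth_rate * treatment.birth_rate_factor`` starting
    at ``onset_dpt`` and observed up to ``max(sessions)``, so the
    cumulative count at session t is Poisson with mean
    ``rate * max(0, t - onset)``.
    """
    if birth_rate < 0 or elongation < 0:
        raise ConfigError("birth_rate and elongation must be non-negative")
    if list(sessions) != sorted(sessions):
        raise ConfigError("sessions must be sorted ascending")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    horizon = float(max(sessions))
    rate = birth_rate * treatment.birth_rate_factor
    span = max(0.0, horizon - onset_dpt)
    n = rng.poisson(rate * span) if rate * span > 0 else 0
    births = np.sort(onset_dpt + rng.uniform(0.0, span, size=n)) if n else np.array([])

    mu, sigma = per_sprout_rate_params(elongation * treatment.elongation_factor,
                                       elongation_cv)

    # sprouts emerge from well-separated anchor points on the terminal
    # wall and head into the wound band with a small lateral tilt, so
    # rendered sprouts stay resolvable as distinct skeleton branches
    sprouts: list[SproutRecord] = []
    anchor_order: dict[str, list] = {}
    for k, b in enumerate(births):
        stump = scene.distal_stumps[k % len(scene.distal_stumps)]
        anchors = scene.sprout_anchors.get(
            stump.vessel_id,
            [(stump.terminal_um[0], stump.terminal_um[1] - stump.radius_um)])
        if stump.vessel_id not in anchor_order:
            anchor_order[stump.vessel_id] = list(rng.permutation(len(anchors)))
        order = anchor_order[stump.vessel_id]
        origin = anchors[order[(k // len(scene.distal_stumps)) % len(anchors)]]
        origin = (float(origin[0]), float(origin[1]))
        theta = rng.uniform(np.deg2rad(-6.0), np.deg2rad(6.0))
        direction = (-float(np.cos(theta)), -float(np.sin(theta)))
        rate_k = float(rng.lognormal(mu, sigma)) if np.isfinite(mu) else 0.0
        sprouts.append(SproutRecord(
            sprout_id=f"{scene.scene_id}-s{k}",
            side="distal",
            parent_stump=stump.vessel_id,
            birth_dpt=float(b),
            elongation_um_per_day=rate_k,
            origin_um=origin,
            direction=direction,
        ))
    return sprouts


def assign_perfusion(
    sprouts: list[SproutRecord],
    p_perfused: float = 2.0 / 3.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> list[SproutRecord]:
    """Independently flag each sprout perfused with probability ``p_perfused``.

    The flag is constant over time: the perfused/total ratio of the
    cohort stays flat across the observation period.
    """
    if not 0.0 <= p_perfused <= 1.0:
        raise ConfigError("p_perfused must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flags = rng.random(len(sprouts)) < p_perfused
    return [replace(s, is_perfused=bool(f)) for s, f in zip(sprouts, flags)]
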