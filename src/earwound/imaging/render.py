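"""Render synthetic two-channel image series from ground truth.

Vessels are drawn as soft-edged tubes (sigmoid radial profile) on the
pixel grid, with a Gaussian extent in z around each vessel's depth.
The green channel carries the intrinsic GCaMP baseline of arteries and
sprouts (veins are GCaMP-negative and appear only in red); in calcium
mode regional transients modulate it multiplicatively.  The red channel
is the intravascular tracer: each vascular compartment fills from its
arrival time with an exponential-saturation front.  Shot (Poisson) and
Gaussian read noise are added last.
"""

from __future__ import annotations

import numpy as np

from ..config import ConfigError, DEFAULTS
from ..sim.calcium_truth import CalciumEventTrain
from ..sim.perfusion_truth import PerfusionGroundTruth, is_censored
from ..sim.scene import VascularScene, Vessel
from ..sim.sprouting import SproutRecord
from .series import ImageSeries

GREEN_AMP = 150.0
RED_AMP = 150.0
READ_NOISE_SD = 2.0


def tube_profile(shape: tuple[int, int], polyline_px: np.ndarray,
                 radius_px: float, edge_px: float = 0.5) -> np.ndarray:
    """Soft tube: 1 inside the lumen, sigmoid falloff at the wall."""
    ny, nx = shape
    pts = np.asarray(polyline_px, dtype=float)
    dmin = np.full(shape, np.inf)
    margin = radius_px + 4 * edge_px + 1
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.maximum(np.minimum(a, b) - margin, 0).astype(int)
        hi = np.minimum(np.maximum(a, b) + margin + 1, [ny, nx]).astype(int)
        if (hi <= lo).any():
            continue
        r = rows[lo[0]:hi[0]]
        c = cols[:, lo[1]:hi[1]]
        ab = b - a
        denom = float(ab @ ab)
        pr = r - a[0]
        pc = c - a[1]
        if denom == 0.0:
            d = np.hypot(pr, pc)
        else:
            t = np.clip((pr * ab[0] + pc * ab[1]) / denom, 0.0, 1.0)
            d = np.hypot(pr - t * ab[0], pc - t * ab[1])
        view = dmin[lo[0]:hi[0], lo[1]:hi[1]]
        np.minimum(view, d, out=view)
    profile = 1.0 / (1.0 + np.exp((dmin - radius_px) / edge_px))
    profile[profile < 1e-2] = 0.0  # hard support: no infinite tails
    return profile


def _um_to_px(polyline_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    pts = np.asarray(polyline_um, dtype=float)
    return np.stack([pts[:, 1], pts[:, 0]], axis=1) / pixel_size_um  # (row, col)


def _z_weights(n_z: int, z_step_um: float, z_center_um: float,
               radius_um: float) -> np.ndarray:
    z = np.arange(n_z) * z_step_um
    return np.exp(-0.5 * ((z - z_center_um) / max(radius_um, 1e-6)) ** 2)


class _Comp:
    """A renderable compartment: 2-D footprint, z profile, fill time."""

    def __init__(self, footprint, zw, arrival_s=None):
        self.footprint = footprint
        self.zw = zw
        self.arrival_s = arrival_s


def _vessel_comp(v: Vessel, shape, px, n_z, z_step, arrival_s=None,
                 sub_polyline_um=None) -> _Comp:
    poly = sub_polyline_um if sub_polyline_um is not None else v.polyline_um
    fp = tube_profile(shape, _um_to_px(poly, px), v.radius_um / px)
    return _Comp(fp, _z_weights(n_z, z_step, v.z_um, v.radius_um), arrival_s)


def _sprout_comp(s: SproutRecord, dpt, shape, px, n_z, z_step, radius_um,
                 arrival_s=None) -> _Comp | None:
    if s.length_at(dpt) <= 0:
        return None
    fp = tube_profile(shape, _um_to_px(s.path_at(dpt), px), radius_um / px)
    return _Comp(fp, _z_weights(n_z, z_step, 8.0, radius_um), arrival_s)


def _split_stump(v: Vessel, frac_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a straight stump at a geodesic distance from its terminal."""
    pts = np.asarray(v.polyline_um, dtype=float)
    far, term = pts[0], pts[-1]
    u = term - far
    length = float(np.linalg.norm(u))
    cut = term - u / length * min(frac_um, length)
    return np.array([far, cut]), np.array([cut, term])


def render_series(
    scene: VascularScene,
    truth: PerfusionGroundTruth | dict | None = None,
    mode: str = "anatomy",
    res: int = 256,
    seed: int | np.random.Generator = 0,
    sprouts: list[SproutRecord] | None = None,
    dpt: float | None = None,
    params: dict | None = None,
    noise: bool = True,
    n_z: int | None = None,
    n_t: int | None = None,
) -> ImageSeries:
    """Render one acquisition.

    ``mode``: "anatomy" (single-timepoint z-stack), "perfusion" (tracer
    time series from a :class:`PerfusionGroundTruth`) or "calcium"
    (GCaMP time series from ``{"proximal": train, "distal": train}``).
    """
    if res not in (128, 256):
        raise ConfigError(f"resolution must be 128 or 256 px, got {res}")
    p = dict(DEFAULTS["imaging"])
    if params:
        p.update(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px = scene.fov_um / res
    shape = (res, res)
    n_z = n_z if n_z is not None else int(p["n_z"])
    z_step = float(p["z_step_um"])
    sprouts = sprouts or []
    sprout_r = DEFAULTS["sprouting"]["sprout_radius_um"]
    if dpt is None:
        dpt = truth.dpt if isinstance(truth, PerfusionGroundTruth) else 8.0

    if mode == "anatomy":
        period = p["frame_period_s"]
        n_t = 1
        green = np.zeros((n_t, n_z, *shape), dtype=float)
        red = np.zeros_like(green)
        for v in scene.gcamp_vessels():
            c = _vessel_comp(v, shape, px, n_z, z_step)
            green[0] = np.maximum(green[0], GREEN_AMP * c.footprint * c.zw[:, None, None])
        for s in sprouts:
            c = _sprout_comp(s, dpt, shape, px, n_z, z_step, sprout_r)
            if c is not None:
                green[0] = np.maximum(green[0], GREEN_AMP * c.footprint * c.zw[:, None, None])
        n_baseline = 0

    elif mode == "perfusion":
        if not isinstance(truth, PerfusionGroundTruth):
            raise ConfigError("perfusion mode needs a PerfusionGroundTruth")
        period = p["frame_period_s"]
        n_t = n_t if n_t is not None else truth.n_frames
        tau = p["tracer_fill_tau_s"]
        times = np.arange(n_t) * period
        comps = _perfusion_compartments(scene, sprouts, truth, shape, px,
                                        n_z, z_step, sprout_r)
        green = np.zeros((n_t, n_z, *shape), dtype=float)
        anat = np.zeros((n_z, *shape), dtype=float)
        for v in scene.gcamp_vessels():
            c = _vessel_comp(v, shape, px, n_z, z_step)
            anat = np.maximum(anat, GREEN_AMP * c.footprint * c.zw[:, None, None])
        for s in sprouts:
            c = _sprout_comp(s, dpt, shape, px, n_z, z_step, sprout_r)
            if c is not None:
                anat = np.maximum(anat, GREEN_AMP * c.footprint * c.zw[:, None, None])
        green[:] = anat[None]
        red = np.zeros((n_t, n_z, *shape), dtype=float)
        for c in comps:
            if c.arrival_s is None or is_censored(c.arrival_s):
                continue
            fill = np.clip(1.0 - np.exp(-(times - c.arrival_s) / tau), 0.0, None)
            fill[times < c.arrival_s] = 0.0
            # restrict the update to the footprint's bounding box
            rows = np.flatnonzero(c.footprint.max(axis=1) > 1e-3)
            cols = np.flatnonzero(c.footprint.max(axis=0) > 1e-3)
            if not len(rows) or not len(cols):
                continue
            r0, r1 = rows[0], rows[-1] + 1
            c0, c1 = cols[0], cols[-1] + 1
            vol = RED_AMP * c.footprint[None, r0:r1, c0:c1] * c.zw[:, None, None]
            slab = red[:, :, r0:r1, c0:c1]
            np.maximum(slab, fill[:, None, None, None] * vol[None], out=slab)
        n_baseline = int(p["n_baseline_frames"])

    elif mode == "calcium":
        if not isinstance(truth, dict):
            raise ConfigError("calcium mode needs {'proximal': train, 'distal': train}")
        cal = DEFAULTS["calcium"]
        period = cal["frame_period_s"]
        any_train: CalciumEventTrain = next(iter(truth.values()))
        n_t = n_t if n_t is not None else int(round(any_train.session_s / period))
        times = np.arange(n_t) * period
        n_z = 1
        anat = np.zeros(shape, dtype=float)
        for v in scene.gcamp_vessels():
            c = _vessel_comp(v, shape, px, 1, z_step)
            anat = np.maximum(anat, GREEN_AMP * c.footprint)
        for s in sprouts:
            c = _sprout_comp(s, dpt, shape, px, 1, z_step, sprout_r)
            if c is not None:
                anat = np.maximum(anat, GREEN_AMP * c.footprint)
        x_um = (np.arange(res) + 0.5) * px
        wound_mid = (scene.wound_x0_um + scene.wound_x1_um) / 2.0
        prox_cols = x_um < wound_mid
        green = np.repeat(anat[None], n_t, axis=0)
        for region, train in truth.items():
            dff = np.zeros(n_t)
            for t0, a in zip(train.event_times_s, train.amplitudes_dff):
                m = times >= t0
                dff[m] += a * np.exp(-(times[m] - t0) / train.decay_tau_s)
            colmask = prox_cols if region == "proximal" else ~prox_cols
            green[:, :, colmask] *= (1.0 + dff)[:, None, None]
        green = green[:, None]  # single z-plane
        red = np.zeros_like(green)
        n_baseline = 0

    else:
        raise ConfigError(f"unknown render mode {mode!r}")

    if noise:
        green = rng.poisson(np.clip(green, 0, None)).astype(float)
        red = rng.poisson(np.clip(red, 0, None)).astype(float)
        green += rng.normal(0.0, READ_NOISE_SD, size=green.shape)
        red += rng.normal(0.0, READ_NOISE_SD, size=red.shape)
        green = np.clip(green, 0, None)
        red = np.clip(red, 0, None)

    return ImageSeries(
        frames={"green": green, "red": red},
        frame_period_s=period,
        pixel_size_um=px,
        z_step_um=z_step,
        n_baseline_frames=n_baseline,
    )


def _perfusion_compartments(scene, sprouts, truth, shape, px, n_z, z_step,
                            sprout_r) -> list[_Comp]:
    t = truth.true_arrival_s
    comps: list[_Comp] = []
    mid_um = (250.0 + 50.0) / 2.0 + 50.0  # split between the paired ROIs
    for v in scene.proximal_stumps:
        far, near = _split_stump(v, mid_um)
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, t.get("A"), far))
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, t.get("B"), near))
    for v in scene.distal_stumps:
        far, near = _split_stump(v, mid_um)
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, t.get("C"), near))
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, t.get("D"), far))
    for v in scene.terminal_bars:
        # the cut face fills with the wound-side compartment
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, t.get("C")))
    vein_arrival = DEFAULTS["perfusion"]["baseline_s"] + 2.0
    for v in scene.veins:
        comps.append(_vessel_comp(v, shape, px, n_z, z_step, vein_arrival))
    finite = [x for x in t.values() if not is_censored(x)]
    sprout_fill = (t["C"] if not is_censored(t.get("C", np.nan))
                   else (max(finite) if finite else np.nan)) + 0.3
    for s in sprouts:
        if not s.is_perfused:
            continue
        c = _sprout_comp(s, truth.dpt, shape, px, n_z, z_step, sprout_r,
                         arrival_s=sprout_fill)
        if c is not None:
            comps.append(c)
    return comps


def render_colocalization(
    scene: VascularScene,
    sprouts: list[SproutRecord],
    dpt: float = 8.0,
    res: int = 256,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """End-state (green, red) z-compressed projections for sprout counting.

    Green shows all GCaMP structures; red shows the tracer-filled
    steady state: stumps, veins and the *perfused* sprouts only.
    """
    if res not in (128, 256):
        raise ConfigError(f"resolution must be 128 or 256 px, got {res}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px = scene.fov_um / res
    shape = (res, res)
    sprout_r = DEFAULTS["sprouting"]["sprout_radius_um"]
    green = np.zeros(shape)
    red = np.zeros(shape)
    for v in scene.gcamp_vessels():
        fp = tube_profile(shape, _um_to_px(v.polyline_um, px), v.radius_um / px)
        green = np.maximum(green, GREEN_AMP * fp)
        red = np.maximum(red, RED_AMP * fp)
    for v in scene.veins:
        fp = tube_profile(shape, _um_to_px(v.polyline_um, px), v.radius_um / px)
        red = np.maximum(red, RED_AMP * fp)
    for s in sprouts:
        if s.length_at(dpt) <= 0:
            continue
        fp = tube_profile(shape, _um_to_px(s.path_at(dpt), px), sprout_r / px)
        green = np.maximum(green, GREEN_AMP * fp)
        if s.is_perfused:
            red = np.maximum(red, RED_AMP * fp)
    if noise:
        green = np.clip(rng.poisson(green) + rng.normal(0, READ_NOISE_SD, shape), 0, None)
        red = np.clip(rng.poisson(red) + rng.normal(0, READ_NOISE_SD, shape), 0, None)
    return green, red
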