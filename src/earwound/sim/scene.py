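"""Geometric model of a transsected-artery wound scene.

The scene lives on a calibrated micrometre grid covering the imaging
field of view (default 1 x 1 mm).  The wound is an axis-aligned band of
default width 300 um across the middle of the FOV; each transsected
artery contributes a proximal stump (upstream of the cut, terminating on
the proximal wound edge) and a distal stump (terminating on the distal
edge).  Veins run parallel to the arteries and carry no GCaMP signal.

Axis convention: ``x`` is the proximal-to-distal axis (x = 0 is the most
proximal edge of the FOV), ``y`` is lateral.  In pixel space, ``x`` maps
to columns and ``y`` to rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..config import ConfigError, DEFAULTS


@dataclass
class Vessel:
    """A vessel centreline with a constant radius.

    ``polyline_um`` is an (N, 2) array of (x, y) vertices in micrometres;
    ``terminal_um`` is the point where a stump meets the wound edge (None
    for uncut vessels such as veins).  ``z_um`` is the depth of the
    centreline, used when rendering three-dimensional stacks.
    """

    vessel_id: str
    kind: str  # "artery_proximal" | "artery_distal" | "vein"
    polyline_um: np.ndarray
    radius_um: float
    terminal_um: tuple[float, float] | None = None
    z_um: float = 8.0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["polyline_um"] = np.asarray(self.polyline_um).tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "Vessel":
        d = dict(d)
        d["polyline_um"] = np.asarray(d["polyline_um"], dtype=float)
        if d["terminal_um"] is not None:
            d["terminal_um"] = tuple(d["terminal_um"])
        return cls(**d)


@dataclass
class VascularScene:
    scene_id: str
    fov_um: float
    wound_x0_um: float
    wound_x1_um: float
    proximal_stumps: list[Vessel] = field(default_factory=list)
    distal_stumps: list[Vessel] = field(default_factory=list)
    #: short GCaMP-positive segments running along the cut face of each
    #: distal stump; sprout anchor points sit on their walls
    terminal_bars: list[Vessel] = field(default_factory=list)
    veins: list[Vessel] = field(default_factory=list)
    anastomosis_sites: list[tuple[str, str, tuple[float, float]]] = field(default_factory=list)
    #: per distal stump: well-separated points on the terminal wall from
    #: which sprouts emerge into the wound band
    sprout_anchors: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def wound_width_um(self) -> float:
        return self.wound_x1_um - self.wound_x0_um

    def all_vessels(self) -> list[Vessel]:
        return [*self.proximal_stumps, *self.distal_stumps,
                *self.terminal_bars, *self.veins]

    def gcamp_vessels(self) -> list[Vessel]:
        """Arterial (GCaMP-positive) structures; excludes veins."""
        return [*self.proximal_stumps, *self.distal_stumps, *self.terminal_bars]

    def to_json(self, path: str | Path) -> None:
        data = {
            "scene_id": self.scene_id,
            "fov_um": self.fov_um,
            "wound_x0_um": self.wound_x0_um,
            "wound_x1_um": self.wound_x1_um,
            "rng_seed": self.rng_seed,
            "proximal_stumps": [v.to_jsonable() for v in self.proximal_stumps],
            "distal_stumps": [v.to_jsonable() for v in self.distal_stumps],
            "terminal_bars": [v.to_jsonable() for v in self.terminal_bars],
            "veins": [v.to_jsonable() for v in self.veins],
            "anastomosis_sites": [
                [sid, vid, list(pos)] for sid, vid, pos in self.anastomosis_sites
            ],
            "sprout_anchors": {k: [list(p) for p in v]
                               for k, v in self.sprout_anchors.items()},
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VascularScene":
        data = json.loads(Path(path).read_text())
        return cls(
            scene_id=data["scene_id"],
            fov_um=data["fov_um"],
            wound_x0_um=data["wound_x0_um"],
            wound_x1_um=data["wound_x1_um"],
            rng_seed=data["rng_seed"],
            proximal_stumps=[Vessel.from_jsonable(v) for v in data["proximal_stumps"]],
            distal_stumps=[Vessel.from_jsonable(v) for v in data["distal_stumps"]],
            terminal_bars=[Vessel.from_jsonable(v) for v in data.get("terminal_bars", [])],
            veins=[Vessel.from_jsonable(v) for v in data["veins"]],
            anastomosis_sites=[
                (sid, vid, tuple(pos)) for sid, vid, pos in data["anastomosis_sites"]
            ],
            sprout_anchors={k: [tuple(p) for p in v]
                            for k, v in data.get("sprout_anchors", {}).items()},
        )


def make_scene(seed: int, n_arteries: int = 1, params: dict | None = None,
               scene_id: str | None = None) -> VascularScene:
    """Construct a deterministic wound scene.

    Arteries are laid out as near-horizontal centrelines cut by the wound
    band; each artery is paired with a parallel vein offset laterally, so
    every stump has at least one vein within anastomosis reach.
    """
    p = dict(DEFAULTS["scene"])
    if params:
        p.update(params)
    fov = float(p["fov_um"])
    w = float(p["wound_width_um"])
    if w >= fov:
        raise ConfigError("scene.wound_width_um must be smaller than scene.fov_um")
    if n_arteries < 1:
        raise ConfigError("n_arteries must be >= 1")

    rng = np.random.default_rng(seed)
    x0 = (fov - w) / 2.0
    x1 = x0 + w

    # lateral positions, keeping head-room for veins and sprouts
    lo, hi = 0.22 * fov, 0.78 * fov
    base = np.linspace(lo, hi, n_arteries + 2)[1:-1]
    ys = base + rng.uniform(-0.02 * fov, 0.02 * fov, size=n_arteries)

    scene = VascularScene(
        scene_id=scene_id or f"scene-{seed}",
        fov_um=fov, wound_x0_um=x0, wound_x1_um=x1, rng_seed=int(seed),
    )
    r_a = float(p["artery_radius_um"])
    r_v = float(p["vein_radius_um"])
    off = float(p["vein_offset_um"])
    n_anchor = 8
    for i, y in enumerate(ys):
        y = float(y)
        # terminal bar along the cut edge, kept inside the FOV
        bar_len = min(300.0, 0.3 * fov, y - 10.0)
        prox = Vessel(
            vessel_id=f"artery{i}_prox", kind="artery_proximal",
            polyline_um=np.array([[0.0, y], [x0, y]]),
            radius_um=r_a, terminal_um=(x0, y), z_um=8.0,
        )
        # the distal stump ends in a short bar along the distal wound
        # edge (the cut face); sprouts emerge from this terminal bar
        bar_x = x1 + 2.0
        dist = Vessel(
            vessel_id=f"artery{i}_dist", kind="artery_distal",
            polyline_um=np.array([[fov, y], [bar_x, y]]),
            radius_um=r_a, terminal_um=(x1, y), z_um=8.0,
        )
        bar = Vessel(
            vessel_id=f"artery{i}_bar", kind="artery_distal",
            polyline_um=np.array([[bar_x, y], [bar_x, y - bar_len]]),
            radius_um=r_a, terminal_um=None, z_um=8.0,
        )
        scene.terminal_bars.append(bar)
        anchors = [(bar_x - r_a, y - (15.0 + k * (bar_len - 30.0) / (n_anchor - 1)))
                   for k in range(n_anchor)]
        scene.sprout_anchors[dist.vessel_id] = anchors
        vein = Vessel(
            vessel_id=f"vein{i}", kind="vein",
            polyline_um=np.array([[0.0, y + off], [fov, y + off]]),
            radius_um=r_v, terminal_um=None, z_um=4.0,
        )
        scene.proximal_stumps.append(prox)
        scene.distal_stumps.append(dist)
        scene.veins.append(vein)
        scene.anastomosis_sites.append(
            (prox.vessel_id, vein.vessel_id, (x0 - 30.0, y + off / 2.0)))
        scene.anastomosis_sites.append(
            (dist.vessel_id, vein.vessel_id, (x1 + 30.0, y + off / 2.0)))

    _check_scene(scene)
    return scene


def _check_scene(scene: VascularScene) -> None:
    for v in scene.proximal_stumps:
        if not np.isclose(v.terminal_um[0], scene.wound_x0_um):
            raise ConfigError(f"{v.vessel_id}: terminal not on proximal wound edge")
    for v in scene.distal_stumps:
        if not np.isclose(v.terminal_um[0], scene.wound_x1_um):
            raise ConfigError(f"{v.vessel_id}: terminal not on distal wound edge")
    for v in scene.all_vessels():
        if v.radius_um <= 0:
            raise ConfigError(f"{v.vessel_id}: non-positive radius")
        pts = np.asarray(v.polyline_um)
        if pts.min() < -1e-9 or pts.max() > scene.fov_um + 1e-9:
            raise ConfigError(f"{v.vessel_id}: centreline outside FOV")
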