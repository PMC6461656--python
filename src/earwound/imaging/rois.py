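"""ROI placement and mean-intensity trace extraction.

Four square ROIs are placed inside the lumen of the transsected artery,
ordered proximal to distal: A and B in the proximal stump (250 and
50 um from the proximal wound edge), C and D mirrored in the distal
stump (50 and 250 um from the distal edge).  Region masks split the
field into proximal / wound / distal bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from ..config import ConfigError
from ..sim.scene import VascularScene
from .series import ImageSeries

ROI_OFFSETS_UM = {"A": 250.0, "B": 50.0, "C": 50.0, "D": 250.0}


class PlacementError(ValueError):
    pass


@dataclass
class RoiSet:
    """Labelled polygons (px, (row, col)) plus proximal/wound/distal masks."""

    polygons: dict[str, np.ndarray]
    region_masks: dict[str, np.ndarray]
    pixel_size_um: float
    shape: tuple[int, int]
    coordinate_convention: str = "0-based (row, col), origin top-left"

    def to_json(self, path: str | Path) -> None:
        items = [{"label": lbl, "polygon": np.asarray(poly).tolist(), "kind": "roi"}
                 for lbl, poly in self.polygons.items()]
        for name, mask in self.region_masks.items():
            # regions are axis-aligned bands; store their bounding polygon
            rr, cc = np.nonzero(mask)
            poly = [[0, int(cc.min())], [0, int(cc.max()) + 1],
                    [self.shape[0], int(cc.max()) + 1], [self.shape[0], int(cc.min())]]
            items.append({"label": name, "polygon": poly, "kind": "region"})
        meta = {"pixel_size_um": self.pixel_size_um, "shape": list(self.shape),
                "coordinate_convention": self.coordinate_convention,
                "rois": items}
        Path(path).write_text(json.dumps(meta, indent=1) + "\n")


def place_rois(scene: VascularScene, resolution_px: int = 256,
               offsets_um: dict[str, float] | None = None,
               roi_halfwidth_um: float | None = None,
               artery_index: int = 0) -> RoiSet:
    """Place ROIs A-D on the centreline of one transsected artery.

    Offsets are geodesic distances from the wound edge along the stump
    centreline.  Raises :class:`PlacementError` when a stump is shorter
    than the requested offset.
    """
    if not scene.proximal_stumps or not scene.distal_stumps:
        raise PlacementError("scene needs at least one proximal and one distal stump")
    offsets = dict(ROI_OFFSETS_UM)
    if offsets_um:
        offsets.update(offsets_um)
    px = scene.fov_um / resolution_px
    prox = scene.proximal_stumps[artery_index]
    dist = scene.distal_stumps[artery_index]
    half = roi_halfwidth_um if roi_halfwidth_um is not None else min(
        10.0, 0.6 * prox.radius_um)

    def point_at(stump, dist_um, sign):
        # geodesic offset from the wound edge along the trunk, which
        # runs horizontally away from the wound at the stump's y level
        pts = np.asarray(stump.polyline_um, dtype=float)
        y = float(pts[0][1])  # far (uncut) end defines the trunk level
        edge_x = float(stump.terminal_um[0])
        far_x = float(pts[0][0])
        length = abs(far_x - edge_x)
        if dist_um > length:
            raise PlacementError(
                f"{stump.vessel_id}: stump length {length:.0f} um shorter than "
                f"ROI offset {dist_um:.0f} um")
        return np.array([edge_x + sign * dist_um, y])

    centers_um = {
        "A": point_at(prox, offsets["A"], -1.0),
        "B": point_at(prox, offsets["B"], -1.0),
        "C": point_at(dist, offsets["C"], +1.0),
        "D": point_at(dist, offsets["D"], +1.0),
    }
    polygons = {}
    for lbl, (x, y) in centers_um.items():
        r, c = y / px, x / px  # row = y, col = x
        h = half / px
        polygons[lbl] = np.array([[r - h, c - h], [r - h, c + h],
                                  [r + h, c + h], [r + h, c - h]])

    cols = np.arange(resolution_px)
    x_um = (cols + 0.5) * px
    prox_band = x_um < scene.wound_x0_um
    wound_band = (x_um >= scene.wound_x0_um) & (x_um < scene.wound_x1_um)
    dist_band = x_um >= scene.wound_x1_um
    shape = (resolution_px, resolution_px)
    region_masks = {
        "proximal": np.broadcast_to(prox_band, shape).copy(),
        "wound": np.broadcast_to(wound_band, shape).copy(),
        "distal": np.broadcast_to(dist_band, shape).copy(),
    }
    return RoiSet(polygons=polygons, region_masks=region_masks,
                  pixel_size_um=px, shape=shape)


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    poly = np.asarray(polygon, dtype=float)
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def extract_trace(series: ImageSeries | np.ndarray, roi: np.ndarray,
                  channel: str = "red") -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean intensity over the ROI polygon.

    3-D stacks are z-compressed (maximum-intensity projection) before
    extraction.  Returns ``(times_s, trace)``; raises ``ValueError`` for
    an ROI containing no pixel centres.
    """
    if isinstance(series, ImageSeries):
        frames = series.projection(channel)
        times = series.times_s
    else:
        frames = np.asarray(series)
        if frames.ndim == 4:
            frames = frames.max(axis=1)
        times = np.arange(frames.shape[0], dtype=float)
    mask = polygon_mask(roi, frames.shape[1:])
    if not mask.any():
        raise ValueError("ROI polygon contains no pixel centres")
    trace = frames[:, mask].mean(axis=1)
    return times, trace
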