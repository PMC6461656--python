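"""Automated sprout detection and morphometry on anatomical stacks.

Replaces the study's manual Fiji measurements: the green (GCaMP)
channel is z-compressed, segmented (Gaussian smoothing, Otsu threshold,
morphological clean-up) and skeletonized; sprouts are skeleton branches
that attach to a stump trunk and enter the wound band, and sprout
length is the geodesic wall-to-tip distance along the branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, opening, remove_small_objects, skeletonize

import pandas as pd

from .config import ConfigError, DEFAULTS

__all__ = ["SproutMeasurement", "segment_vessels", "detect_sprouts",
           "measure_length", "summarize_sprouts"]

_SQRT2 = float(np.sqrt(2.0))
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SproutMeasurement:
    """One detected sprout: side, wall-to-tip length, skeleton path."""

    sprout_id: str
    side: str
    length_um: float
    tip_xy: tuple[int, int]  # (row, col)
    skeleton_path: np.ndarray  # (N, 2) int pixels, wall -> tip
    perfused: bool | None = None


def segment_vessels(green_stack: np.ndarray, sigma_px: float = 1.0,
                    min_size_px: int = 20) -> np.ndarray:
    """Binary vessel mask from the green channel.

    Maximum-intensity z-projection, Gaussian smoothing, Otsu threshold,
    opening with a radius-1 disk, and removal of components below
    ``min_size_px``.  A blank image yields an empty mask with a warning
    (not an error).  The Otsu threshold makes the mask invariant to a
    global intensity scale.
    """
    img = np.asarray(green_stack, dtype=float)
    while img.ndim > 2:
        img = img.max(axis=0)
    sm = gaussian(img, sigma=sigma_px, preserve_range=True)
    if np.ptp(sm) < 1e-12:
        warnings.warn("blank image: no foreground after threshold")
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(sm)
    # a threshold within the noise band means there is no foreground:
    # on blank images Otsu merely splits the noise distribution
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    if thr - med < 5 * 1.4826 * mad:
        warnings.warn("blank image: no foreground after threshold")
        return np.zeros(img.shape, dtype=bool)
    mask = sm > thr
    mask = opening(mask, disk(1))
    mask = remove_small_objects(mask, max_size=min_size_px - 1)
    if not mask.any():
        warnings.warn("blank image: no foreground after threshold")
    return mask


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    pts = list(zip(*np.nonzero(skeleton)))
    on = set(pts)
    g.add_nodes_from(pts)
    for (r, c) in pts:
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q in on and not g.has_edge((r, c), q):
                g.add_edge((r, c), q, weight=_SQRT2 if dr and dc else 1.0)
    return g


def _walk_to_trunk(g: nx.Graph, start, banned: set, max_steps: int = 30):
    """Follow the out-of-band branch from an entry pixel to the trunk.

    Stops at the first junction (degree >= 3), which is where the
    sprout branch meets the stump centreline.  Returns ``(path,
    junction, ok)``; ``ok`` is False when no junction appears within
    ``max_steps`` pixels, which marks the candidate as the continuation
    of a trunk poking into the wound band rather than a sprout branch.
    """
    path = []
    nbrs = [n for n in g.neighbors(start) if n not in banned]
    if not nbrs:
        return path, None, True  # root attaches right at the band edge
    cur = min(nbrs)
    visited = {start}
    for _ in range(max_steps):
        path.append(cur)
        if g.degree(cur) >= 3:
            return path, cur, True
        visited.add(cur)
        nxt = [n for n in g.neighbors(cur) if n not in visited and n not in banned]
        if not nxt:
            return path, None, True  # dead end: hanging stub, keep it
        cur = min(nxt)
    return path, None, False


def _extend_tip(mask: np.ndarray, path: list, max_steps: int = 12) -> list:
    """March the tip along its terminal direction to the mask boundary.

    Skeletonization erodes branch ends by roughly the tube radius; this
    reconstructs the lost tip.
    """
    if len(path) < 2:
        return []
    a = np.asarray(path[-2], dtype=float)
    b = np.asarray(path[-1], dtype=float)
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        return []
    d /= n
    ext = []
    cur = b.copy()
    for _ in range(max_steps):
        cur = cur + d
        r, c = int(round(cur[0])), int(round(cur[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            break
        ext.append((r, c))
    return ext


def detect_sprouts(
    mask: np.ndarray,
    regions: dict[str, np.ndarray],
    pixel_size_um: float,
    min_length_um: float = DEFAULTS["sprouting"]["min_length_um"],
) -> list[SproutMeasurement]:
    """Sprouts = skeleton branches attached to a stump that enter the wound.

    ``regions`` must provide boolean masks "proximal", "wound" and
    "distal".  Each wound-entry point defines one sprout whose path runs
    from the trunk attachment to the deepest reachable tip (ties broken
    towards the lexicographically smallest pixel, deterministically).
    Branch length is corrected for the trunk radius at the attachment
    (distance-transform estimate) and for skeleton tip erosion.
    """
    for key in ("proximal", "wound", "distal"):
        if key not in regions:
            raise ConfigError(f"missing region mask {key!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    wound = np.asarray(regions["wound"], dtype=bool)
    sides = {"proximal": np.asarray(regions["proximal"], dtype=bool),
             "distal": np.asarray(regions["distal"], dtype=bool)}
    skeleton = skeletonize(mask)
    g = _skeleton_graph(skeleton)
    edt = ndimage.distance_transform_edt(mask)

    inband_nodes = [n for n in g.nodes if wound[n]]
    sub = g.subgraph(inband_nodes)

    measurements: list[SproutMeasurement] = []
    for comp in sorted(nx.connected_components(sub), key=min):
        comp = set(comp)
        # entry pixels: in-band nodes adjacent to out-of-band skeleton
        entries = []
        for node in comp:
            outside = [n for n in g.neighbors(node) if n not in comp and not wound[n]]
            for o in outside:
                side = ("distal" if sides["distal"][o]
                        else "proximal" if sides["proximal"][o] else None)
                if side:
                    entries.append((node, o, side))
        if not entries:
            continue
        # cluster adjacent entry pixels (one sprout may touch the edge on
        # two neighbouring pixels)
        entries.sort(key=lambda e: e[0])
        clusters: list[list] = []
        for e in entries:
            placed = False
            for cl in clusters:
                if any(max(abs(e[0][0] - f[0][0]), abs(e[0][1] - f[0][1])) <= 2
                       for f in cl) and cl[0][2] == e[2]:
                    cl.append(e)
                    placed = True
                    break
            if not placed:
                clusters.append([e])

        for ci, cl in enumerate(clusters):
            node0, out0, side = cl[0]
            dist = nx.single_source_dijkstra_path_length(
                sub.subgraph(comp), node0, weight="weight")
            tip = min((n for n in dist), key=lambda n: (-dist[n], n))
            inband_path = nx.dijkstra_path(sub.subgraph(comp), node0, tip,
                                           weight="weight")
            root_path, junction, ok = _walk_to_trunk(g, out0, banned=comp)
            if not ok:
                continue  # trunk continuation, not a sprout branch
            full = list(reversed(root_path)) + [node0] + inband_path[1:]
            # reconstruct the tip eroded by skeletonization: march to the
            # mask boundary, then pull back by the local tube radius
            # (the rounded cap extends one radius beyond the centreline)
            ext = _extend_tip(mask, full)
            pullback = float(edt[tuple(np.asarray(full[-1], dtype=int))])
            keep_ext = max(0, int(round(len(ext) - pullback)))
            full = full + ext[:keep_ext]
            # trim the trunk-lumen portion so the path starts at the
            # parent wall: trunk pixels are systematically thicker than
            # the branch, whose half-width the in-band pixels estimate
            half_w = float(np.median([edt[p] for p in inband_path]))
            k = 0
            while k < len(full) - 2 and edt[full[k]] > 1.3 * half_w:
                k += 1
            full = full[k:]
            path = np.asarray(full, dtype=int)
            length_px = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
            length_um = max(0.0, length_px * pixel_size_um)
            if length_um < min_length_um:
                continue
            measurements.append(SproutMeasurement(
                sprout_id=f"sprout_{len(measurements)}",
                side=side,
                length_um=length_um,
                tip_xy=tuple(path[-1]),
                skeleton_path=path,
            ))
    return measurements


def measure_length(skeleton_path: np.ndarray, pixel_size_um: float) -> float:
    """Geodesic path length in um (Euclidean inter-vertex steps)."""
    path = np.asarray(skeleton_path, dtype=float)
    if len(path) == 0:
        raise ValueError("empty skeleton path")
    if len(path) == 1:
        warnings.warn("single-point path has zero length")
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)) * pixel_size_um)


def summarize_sprouts(measurements: list[SproutMeasurement], animal_id: str,
                      dpt: float, group: str = "control") -> pd.DataFrame:
    """Tidy cohort rows: per-side counts and the mean length.

    Zero-sprout sessions yield count 0 and a *missing* mean length (not
    zero) so that length models are not biased towards zero.
    """
    rows = []

    def add(metric, value, censored=0):
        rows.append(dict(animal_id=animal_id, group=group, dpt=float(dpt),
                         metric=metric, value=value, censored=censored))

    for side in ("distal", "proximal"):
        add(f"sprout_count_{side}",
            float(sum(1 for m in measurements if m.side == side)))
    lengths = [m.length_um for m in measurements]
    add("mean_length_um", float(np.mean(lengths)) if lengths else np.nan,
        censored=0 if lengths else 1)
    return pd.DataFrame(rows)
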