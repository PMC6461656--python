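"""Two-channel image series container and TIFF + sidecar-JSON round trip.

Stacks are stored as multi-page TIFF with one page per (t, z, channel),
t-major ordering, and a sidecar JSON carrying the acquisition metadata
(frame period, pixel size, z spacing, channel order, baseline length).
Pixel coordinates are 0-based (row, col) with the origin at the top
left; this convention is recorded in the metadata of every file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

REQUIRED_KEYS = ("frame_period_s", "pixel_size_um", "z_step_um",
                 "channel_order", "page_order", "n_baseline_frames")


class MetadataError(ValueError):
    pass


@dataclass
class ImageSeries:
    """Time-ordered 2-channel stack: frames[channel] is (n_t, n_z, ny, nx)."""

    frames: dict[str, np.ndarray]
    frame_period_s: float
    pixel_size_um: float
    z_step_um: float = 2.0
    n_baseline_frames: int = 30
    channel_order: tuple[str, ...] = ("green", "red")
    coordinate_convention: str = "0-based (row, col), origin top-left"

    def __post_init__(self):
        shapes = {ch: np.asarray(a).shape for ch, a in self.frames.items()}
        if len(set(shapes.values())) > 1:
            raise MetadataError(f"channel shapes differ: {shapes}")
        for ch, a in self.frames.items():
            if np.asarray(a).ndim != 4:
                raise MetadataError(f"channel {ch!r} is not (t, z, y, x)")

    @property
    def n_t(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    @property
    def n_z(self) -> int:
        return next(iter(self.frames.values())).shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_t) * self.frame_period_s

    def projection(self, channel: str) -> np.ndarray:
        """Maximum-intensity projection over z: (n_t, ny, nx)."""
        return np.asarray(self.frames[channel]).max(axis=1)


def write_series(series: ImageSeries, path: str | Path) -> None:
    """Write TIFF pages ordered (t, z, channel) plus a sidecar JSON."""
    path = Path(path)
    order = series.channel_order
    arrs = [np.asarray(series.frames[ch]) for ch in order]
    n_t, n_z, ny, nx = arrs[0].shape
    pages = np.stack(arrs, axis=2).reshape(n_t * n_z * len(order), ny, nx)
    tifffile.imwrite(path, pages)
    meta = {
        "frame_period_s": series.frame_period_s,
        "pixel_size_um": series.pixel_size_um,
        "z_step_um": series.z_step_um,
        "channel_order": list(order),
        "page_order": "tzc",
        "n_baseline_frames": series.n_baseline_frames,
        "n_t": n_t,
        "n_z": n_z,
        "coordinate_convention": series.coordinate_convention,
    }
    sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")


def sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def read_series(path: str | Path) -> ImageSeries:
    """Read a TIFF + sidecar pair; lossless for integer data.

    Raises :class:`MetadataError` naming any absent metadata keys or a
    page count inconsistent with the metadata.
    """
    path = Path(path)
    meta_path = sidecar(path)
    if not meta_path.exists():
        raise MetadataError(f"missing sidecar metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in REQUIRED_KEYS if k not in meta]
    if missing:
        raise MetadataError(f"metadata missing keys: {', '.join(missing)}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_t, n_z = int(meta["n_t"]), int(meta["n_z"])
    order = list(meta["channel_order"])
    expected = n_t * n_z * len(order)
    if pages.shape[0] != expected:
        raise MetadataError(
            f"page count {pages.shape[0]} inconsistent with metadata "
            f"(n_t={n_t}, n_z={n_z}, channels={len(order)} -> {expected})")
    ny, nx = pages.shape[1:]
    cube = pages.reshape(n_t, n_z, len(order), ny, nx)
    frames = {ch: cube[:, :, k] for k, ch in enumerate(order)}
    return ImageSeries(
        frames=frames,
        frame_period_s=float(meta["frame_period_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        n_baseline_frames=int(meta["n_baseline_frames"]),
        channel_order=tuple(order),
    )
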