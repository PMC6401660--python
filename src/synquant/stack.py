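"""Calibrated image containers and TIFF I/O.

The package works with two array layouts:

* volumes: ``(channel, z, y, x)`` with physical spacing ``(dz, dy, dx)`` in μm;
* time-lapses: ``(time, y, x)`` with spacing ``(dy, dx)`` in μm and a frame
  interval in seconds.

Physical coordinates follow the voxel-center convention: the center of the
voxel with index ``i`` along an axis with spacing ``s`` sits at ``(i + 0.5) * s``
μm. All landmark coordinates and distances in the package are expressed in μm,
never in voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError

VOLUME = "volume"
TIMELAPSE = "timelapse"

_INFO_KEY = "synquant"


@dataclass
class ImageStack:
    """A calibrated multi-channel volume or single-channel time-lapse.

    Parameters
    ----------
    data
        ``(C, Z, Y, X)`` float/integer array for volumes, ``(T, Y, X)`` for
        time-lapses. Intensities must be non-negative.
    spacing
        Physical size of one voxel per *spatial* axis, μm: ``(dz, dy, dx)``
        for volumes, ``(dy, dx)`` for time-lapses.
    channel_names
        Ordered channel labels (volumes only); must be unique and match the
        channel axis length.
    frame_interval
        Seconds between frames (time-lapses only).
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    channel_names: tuple[str, ...] | None = None
    frame_interval: float | None = None
    kind: str = VOLUME

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.kind == VOLUME:
            if self.data.ndim != 4:
                raise ValueError("volume stacks must be (channel, z, y, x)")
            if len(self.spacing) != 3:
                raise ValueError("volume spacing must be (dz, dy, dx)")
            if self.channel_names is None:
                self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError("channel_names length must match channel axis")
            if len(set(self.channel_names)) != len(self.channel_names):
                raise ValueError("channel_names must be unique")
        elif self.kind == TIMELAPSE:
            if self.data.ndim != 3:
                raise ValueError("time-lapse stacks must be (time, y, x)")
            if len(self.spacing) != 2:
                raise ValueError("time-lapse spacing must be (dy, dx)")
        else:
            raise ValueError(f"unknown stack kind {self.kind!r}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    # -- convenience ------------------------------------------------------

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a named channel."""
        if self.kind != VOLUME:
            raise ValueError("channel() is only defined for volume stacks")
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {list(self.channel_names)})"
            ) from None
        return self.data[idx]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³ (volumes) or area in μm² (time-lapses)."""
        return float(np.prod(self.spacing))

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (time-lapses)."""
        if self.kind != TIMELAPSE or self.frame_interval is None:
            raise ValueError("times() requires a time-lapse with a frame interval")
        return np.arange(self.data.shape[0]) * float(self.frame_interval)


def voxel_centers(shape: tuple[int, ...], spacing: tuple[float, ...]) -> list[np.ndarray]:
    """Per-axis physical coordinates of voxel centers, μm.

    Returns one 1-D array per axis; broadcast them for full grids.
    """
    return [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing, strict=True)
    ]


def index_to_physical(index, spacing) -> np.ndarray:
    """Voxel index (possibly fractional) → physical μm coordinates."""
    return (np.asarray(index, dtype=float) + 0.5) * np.asarray(spacing, dtype=float)


def physical_to_index(pos, spacing) -> np.ndarray:
    """Physical μm coordinates → fractional voxel index."""
    return np.asarray(pos, dtype=float) / np.asarray(spacing, dtype=float) - 0.5


def sum_projection(volume: np.ndarray, region: np.ndarray | None = None) -> np.ndarray:
    """Sum-project a ``(z, y, x)`` volume along z, optionally restricted to a region.

    The projection conserves total fluorescence: the sum of the projected
    image over the region footprint equals the sum of the 3-D intensities
    over the region itself.
    """
    volume = np.asarray(volume)
    if region is not None:
        volume = np.where(np.asarray(region, bool), volume, 0)
    return volume.sum(axis=0)


# -- TIFF I/O --------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as an ImageJ-style TIFF with calibration metadata.

    Spacing, channel names, frame interval and axis order are stored in the
    ImageJ ``Info`` field as JSON, plus the standard ImageJ ``spacing`` /
    resolution tags so FIJI reads the calibration directly.
    """
    path = Path(path)
    info = {
        "kind": stack.kind,
        "spacing_um": list(stack.spacing),
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
        "frame_interval_s": stack.frame_interval,
    }
    if stack.kind == VOLUME:
        axes = "ZCYX"  # ImageJ hyperstacks require TZCYXS ordering
        dz, dy, dx = stack.spacing
        data = np.moveaxis(stack.data, 0, 1)
    else:
        axes = "TYX"
        dy, dx = stack.spacing
        dz = 1.0
        data = stack.data
    if data.dtype not in (np.float32, np.uint8, np.uint16):
        data = data.astype(np.float32)
    metadata = {
        "axes": axes,
        "spacing": dz,
        "unit": "um",
        "Info": json.dumps({_INFO_KEY: info}),
    }
    if stack.frame_interval is not None:
        metadata["finterval"] = stack.frame_interval
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=metadata,
    )
    return path


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, ...] | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (or any calibrated ImageJ TIFF).

    Axis order is normalized to ``(channel, z, y, x)`` or ``(time, y, x)``.
    Intensities are preserved bit-exactly. Calibration is taken from the
    metadata unless ``spacing_override`` is given; a file with no calibration
    and no override raises :class:`~synquant.errors.CalibrationError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        ij = tif.imagej_metadata or {}

    info = None
    raw_info = ij.get("Info")
    if raw_info:
        try:
            info = json.loads(raw_info).get(_INFO_KEY)
        except (json.JSONDecodeError, AttributeError):
            info = None

    if info is not None:
        kind = info["kind"]
        spacing = tuple(info["spacing_um"])
        names = info.get("channel_names")
        finterval = info.get("frame_interval_s")
    else:
        # Foreign file: infer layout from the series axes string.
        kind = TIMELAPSE if ("T" in axes and "Z" not in axes and "C" not in axes) else VOLUME
        spacing = None
        names = None
        finterval = ij.get("finterval")
        dz = ij.get("spacing")
        if dz is not None:
            # xy resolution from the first page tags if present
            spacing = (float(dz), 1.0, 1.0)

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise CalibrationError(
            f"{path} carries no physical calibration; pass spacing_override="
            "(dz, dy, dx) in μm (or (dy, dx) for a time-lapse)"
        )
    if frame_interval is not None:
        finterval = frame_interval

    # normalize axes: tifffile may drop singleton axes; volumes come back ZCYX
    if kind == VOLUME:
        if data.ndim == 3:  # single channel volume stored as ZYX
            data = data[None]
        elif data.ndim == 4 and axes[:2] == "ZC":
            data = np.moveaxis(data, 1, 0)
        elif data.ndim == 4 and axes[:2] == "TZ":  # Z mislabeled as T on foreign files
            data = np.moveaxis(data, 1, 0)
    else:
        if data.ndim == 2:
            data = data[None]

    return ImageStack(
        data=data,
        spacing=spacing,
        channel_names=tuple(names) if names else None,
        frame_interval=finterval,
        kind=kind,
    )
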