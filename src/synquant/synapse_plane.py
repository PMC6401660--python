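"""Metrics of the synaptic interface of spreading cells.

A 2-D cell footprint (CellTemp) is partitioned into a concentric central
ellipse of one third of its area (CenterTemp, orientation and aspect
matched to the footprint's second moments) and the peripheral remainder
(PeripheryTemp = CellTemp − CenterTemp). On this partition:

* ``periphery_index`` = (F/A of periphery) / (F/A of whole cell) − 1;
  positive values mean peripheral enrichment, negative central enrichment;
* ``central_fraction`` = F(center)/F(cell), the confinement readout used
  for pSyk at the synapse center.

Time-lapse footprints give per-frame spreading areas (μm²), a spreading
velocity (least-squares slope over the rise window, μm²/min) and
kymographs (distance × time intensity maps along a line through the
centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateWindowError, SegmentationError, UndefinedRatioError
from .segmentation import segment_plane
from .stack import ImageStack

__all__ = [
    "SynapsePartition",
    "build_partition",
    "periphery_index",
    "central_fraction",
    "SpreadingTimecourse",
    "spreading_area_series",
    "spreading_velocity",
    "Kymograph",
    "kymograph",
]


@dataclass
class SynapsePartition:
    """CellTemp / CenterTemp / PeripheryTemp masks of one footprint."""

    cell_template: np.ndarray
    center_template: np.ndarray
    periphery_template: np.ndarray

    def __post_init__(self):
        if (self.center_template & ~self.cell_template).any():
            raise ValueError("center_template must be a subset of cell_template")

    @property
    def center_area_fraction(self) -> float:
        return float(self.center_template.sum() / self.cell_template.sum())


def _mask_moments(mask: np.ndarray):
    """Centroid, principal directions and axis scales of a 2-D mask."""
    pts = np.argwhere(mask).astype(float)  # (n, 2) in (row, col)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return centroid, evals, evecs


def build_partition(cell_mask: np.ndarray, min_pixels: int = 9) -> SynapsePartition:
    """Partition a footprint into a concentric one-third-area center ellipse
    and its periphery.

    The center ellipse sits at the mask centroid with orientation and aspect
    taken from the mask's second moments (a circle for near-circular masks,
    eccentricity < 0.2), scaled by bisection so that its intersection with
    the mask holds one third of the mask area (to within rasterization).
    """
    cell_mask = np.asarray(cell_mask, bool)
    area = int(cell_mask.sum())
    if area < min_pixels:
        raise SegmentationError(
            f"mask of {area} px is too small to rasterize a one-third ellipse"
        )
    n_labels = ndimage.label(cell_mask)[1]
    if n_labels != 1:
        raise SegmentationError(f"cell mask must be connected, found {n_labels} components")

    centroid, evals, evecs = _mask_moments(cell_mask)
    # eccentricity of the equivalent ellipse
    ecc = np.sqrt(max(0.0, 1.0 - evals[0] / evals[1])) if evals[1] > 0 else 0.0
    if ecc < 0.2:
        semi = np.array([1.0, 1.0])
        rot = np.eye(2)
    else:
        semi = np.sqrt(np.maximum(evals, 1e-12))
        semi = semi / semi.max()
        rot = evecs  # columns: minor, major directions

    rows, cols = np.indices(cell_mask.shape)
    rel = np.stack([rows - centroid[0], cols - centroid[1]], axis=-1)
    u = rel @ rot  # coordinates along (minor, major) axes
    quad = (u[..., 0] / semi[0]) ** 2 + (u[..., 1] / semi[1]) ** 2

    target = area / 3.0
    lo, hi = 0.0, float(np.hypot(*cell_mask.shape))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        inside = int(((quad <= mid**2) & cell_mask).sum())
        if inside < target:
            lo = mid
        else:
            hi = mid
    center = (quad <= hi**2) & cell_mask
    return SynapsePartition(
        cell_template=cell_mask,
        center_template=center,
        periphery_template=cell_mask & ~center,
    )


def _densities(image: np.ndarray, partition: SynapsePartition):
    image = np.asarray(image, dtype=float)
    f_cell = image[partition.cell_template].sum()
    if f_cell <= 0:
        raise UndefinedRatioError("no fluorescence inside the cell template")
    return image, f_cell


def periphery_index(image: np.ndarray, partition: SynapsePartition) -> float:
    """Peripheral-enrichment index: (F_per/A_per)/(F_cell/A_cell) − 1."""
    image, f_cell = _densities(image, partition)
    a_cell = partition.cell_template.sum()
    a_per = partition.periphery_template.sum()
    if a_per == 0:
        raise UndefinedRatioError("periphery template is empty")
    f_per = image[partition.periphery_template].sum()
    return float((f_per / a_per) / (f_cell / a_cell) - 1.0)


def central_fraction(image: np.ndarray, partition: SynapsePartition) -> float:
    """Fraction of cellular fluorescence inside the central ellipse, in [0, 1]."""
    image, f_cell = _densities(image, partition)
    return float(image[partition.center_template].sum() / f_cell)


@dataclass
class SpreadingTimecourse:
    """Per-frame spreading areas with optional velocity fit and kymograph."""

    times: np.ndarray  # s
    areas: np.ndarray  # μm²
    empty_frames: np.ndarray  # bool flags for frames with no detectable cell
    velocity: float | None = None  # μm²/min
    fit_window: tuple[float, float] | None = None  # (t_start, t_end), s
    fit_residual_rms: float | None = None
    kymograph: "Kymograph | None" = None


def spreading_area_series(
    timelapse: ImageStack, sigma: float = 1.0
) -> SpreadingTimecourse:
    """Segment each frame and report footprint areas in μm².

    Frames where segmentation fails (no cell) get area 0 and an
    ``empty_frames`` flag rather than aborting the series.
    """
    if timelapse.kind != "timelapse":
        raise ValueError("spreading_area_series expects a (time, y, x) stack")
    px_area = timelapse.spacing[0] * timelapse.spacing[1]
    areas, empty = [], []
    for frame in timelapse.data:
        try:
            mask = segment_plane(frame, sigma=sigma)
            areas.append(mask.sum() * px_area)
            empty.append(False)
        except SegmentationError:
            areas.append(0.0)
            empty.append(True)
    return SpreadingTimecourse(
        times=timelapse.times(),
        areas=np.asarray(areas, dtype=float),
        empty_frames=np.asarray(empty, dtype=bool),
    )


def spreading_velocity(
    timecourse: SpreadingTimecourse,
    window: tuple[float, float] | None = None,
    rise_fraction: float = 0.95,
) -> SpreadingTimecourse:
    """Fit the spreading velocity (μm²/min) over the rise window.

    Default window: from t = 0 to the first frame whose area reaches
    ``rise_fraction`` (95%) of the maximum area, extended to at least three
    frames when the movie has them (so an already-spread or constant
    footprint fits a flat line, velocity 0, instead of failing). The slope
    of the least-squares line of area vs time over the window is converted
    to μm²/min. The window and residuals are recorded on the timecourse.
    """
    t = np.asarray(timecourse.times, dtype=float)
    a = np.asarray(timecourse.areas, dtype=float)
    if window is None:
        stop = int(np.argmax(a >= rise_fraction * a.max()))
        stop = min(max(stop, 2), len(t) - 1)
        window = (float(t[0]), float(t[stop]))
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 3:
        raise DegenerateWindowError(
            f"fit window {window} contains {int(sel.sum())} frames; need >= 3"
        )
    slope, intercept = np.polyfit(t[sel], a[sel], 1)
    resid = a[sel] - (slope * t[sel] + intercept)
    timecourse.velocity = float(slope * 60.0)
    timecourse.fit_window = window
    timecourse.fit_residual_rms = float(np.sqrt(np.mean(resid**2)))
    return timecourse


@dataclass
class Kymograph:
    """Distance × time intensity map along a fixed line through the footprint."""

    data: np.ndarray  # (n_samples, n_frames)
    distances: np.ndarray  # μm, signed along the line (0 at the line center)
    times: np.ndarray  # s
    center: tuple[float, float]  # μm (y, x)
    angle: float  # rad, 0 = +x

    line_definition: str = field(
        default="bilinear samples along the line center ± L/2 at the pixel pitch"
    )


def kymograph(
    timelapse: ImageStack,
    center: tuple[float, float] | None = None,
    angle: float | None = None,
    length: float | None = None,
    sigma: float = 1.0,
) -> Kymograph:
    """Build a kymograph along a line through the cell centroid.

    Defaults: the line passes through the first segmentable frame's centroid
    along its major principal axis and spans the full field of view; each
    column is the bilinearly interpolated intensity profile of one frame,
    sampled at the pixel pitch (``ceil(length / pixel_size)`` samples).
    """
    if timelapse.kind != "timelapse":
        raise ValueError("kymograph expects a (time, y, x) stack")
    dy, dx = timelapse.spacing
    if abs(dy - dx) > 1e-9:
        raise ValueError("kymograph requires square pixels")
    px = dx
    ny, nx = timelapse.data.shape[1:]

    if center is None or angle is None:
        mask = None
        for frame in timelapse.data:
            try:
                mask = segment_plane(frame, sigma=sigma)
                break
            except SegmentationError:
                continue
        if mask is None:
            raise SegmentationError("no segmentable frame to define the kymograph line")
        centroid, evals, evecs = _mask_moments(mask)
        if center is None:
            center = ((centroid[0] + 0.5) * px, (centroid[1] + 0.5) * px)
        if angle is None:
            major = evecs[:, 1]  # (row, col) components of the major axis
            angle = float(np.arctan2(major[0], major[1]))

    if length is None:
        length = float(np.hypot(ny * px, nx * px))
    n_samples = int(np.ceil(length / px))
    s = (np.arange(n_samples) - (n_samples - 1) / 2) * px  # signed μm along line
    yy = center[0] + s * np.sin(angle)
    xx = center[1] + s * np.cos(angle)
    rows = yy / px - 0.5
    cols = xx / px - 0.5
    in_image = (rows >= 0) & (rows <= ny - 1) & (cols >= 0) & (cols <= nx - 1)
    if not in_image.any():
        raise ValueError("kymograph line lies entirely outside the image")

    columns = [
        ndimage.map_coordinates(
            np.asarray(frame, dtype=float), [rows, cols], order=1, mode="constant", cval=0.0
        )
        for frame in timelapse.data
    ]
    return Kymograph(
        data=np.stack(columns, axis=1),
        distances=s,
        times=timelapse.times(),
        center=tuple(center),
        angle=float(angle),
    )
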