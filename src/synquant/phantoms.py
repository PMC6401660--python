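"""Synthetic microscopy phantoms with known ground truth.

Two generators emulate the package's two experimental geometries:

* :func:`generate_conjugate` — a fixed B cell–bead conjugate as a
  multi-channel 3-D stack: a spherical cell with a nucleus, a centrosome,
  a 3 μm antigen-coated bead tangent to the cell surface, and per-channel
  intensity models (tubulin spot, cortical/centrosomal actin, LAMP-1
  lysosome puncta with controllable polarization toward the bead, an OVA
  shell on the bead scaled by the extracted fraction, DAPI nucleus,
  proteasome pools).
* :func:`generate_spreading` — a 2-D time-lapse of a cell spreading on an
  antigen-coated surface, with footprint area following a saturating
  exponential A(t) = A0 + (A_max − A0)(1 − e^(−t/τ)) and a controllable
  fraction of fluorescence in the peripheral ring.

Every scene carries a sidecar truth object (a pydantic model serialized to
JSON) holding all landmark coordinates and model parameters, so each metric
downstream is testable by parameter recovery. Geometry uses spherical
implicit surfaces rasterized on an anisotropic voxel grid (0.5 μm z-steps,
0.1 μm in xy by default); all coordinates are μm, voxel-center convention.

Camera noise is Poisson(photon_scale · expectation)/photon_scale plus
Gaussian read noise; ``photon_scale=None`` renders the noiseless
expectation. Fixed seeds give bit-identical output.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.ndimage import gaussian_filter

from .stack import ImageStack, TIMELAPSE, VOLUME, voxel_centers, write_stack

ChannelName = Literal[
    "tubulin", "actin", "lamp1", "ova", "dapi", "proteasome", "psyk", "lifeact"
]

#: structure parameters each channel model understands, with defaults
DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "tubulin": {"haze_weight": 0.15, "spot_sigma": 0.3},
    "actin": {
        "cyto_weight": 0.25,
        "cortical_shell_weight": 1.0,
        "shell_thickness": 0.3,
        "centrosomal_pool_weight": 0.3,
        "pool_sigma": 0.5,
    },
    "lamp1": {"n_puncta": 40, "punctum_sigma": 0.15, "cap_sigma": 0.3},
    "ova": {"shell_thickness": 0.3},
    "dapi": {},
    "proteasome": {
        "centrosomal_pool_weight": 0.6,
        "pool_sigma": 0.5,
        "cortical_shell_weight": 0.4,
        "shell_thickness": 0.3,
    },
    "psyk": {"cluster_sigma": 1.0},
}


class ChannelModel(BaseModel):
    """Intensity model for one fluorescence channel.

    ``amplitude`` scales the structured signal, ``background`` is a flat
    offset. ``params`` are the structure parameters (see
    :data:`DEFAULT_PARAMS`); missing keys take their defaults. Noise:
    Poisson at ``photon_scale`` photons per intensity unit (``None`` =
    noiseless) plus Gaussian read noise of ``read_sigma``.
    """

    name: ChannelName
    background: float = Field(2.0, ge=0)
    amplitude: float = Field(100.0, ge=0)
    photon_scale: float | None = Field(None, gt=0)
    read_sigma: float = Field(0.0, ge=0)
    params: dict[str, float] = Field(default_factory=dict)

    @field_validator("params")
    @classmethod
    def _nonnegative(cls, v):
        for key, val in v.items():
            if val < 0:
                raise ValueError(f"channel parameter {key} must be >= 0, got {val}")
        return v

    def param(self, key: str) -> float:
        return self.params.get(key, DEFAULT_PARAMS[self.name][key])


def photon_scale_for_snr(snr: float, intensity: float) -> float:
    """Photon scale at which Poisson noise gives the requested SNR.

    For expected intensity ``I`` the Poisson standard deviation is
    ``sqrt(I / photon_scale)``, so SNR = sqrt(I · photon_scale).
    """
    if snr <= 0 or intensity <= 0:
        raise ValueError("snr and intensity must be positive")
    return snr**2 / intensity


def default_channels(
    snr: float | None = None,
    names: tuple[str, ...] = ("tubulin", "actin", "lamp1", "ova", "dapi"),
    overrides: dict[str, dict] | None = None,
) -> dict[str, ChannelModel]:
    """Standard conjugate channel set, optionally with Poisson noise at a given SNR."""
    channels = {}
    for name in names:
        kwargs: dict = {"name": name}
        if name == "ova":
            # anti-OVA staining marks bead-bound antigen only; a diffuse
            # offset would bias extraction multiplicatively
            kwargs["background"] = 0.0
        if snr is not None:
            kwargs["photon_scale"] = photon_scale_for_snr(snr, 100.0)
        if overrides and name in overrides:
            kwargs.update(overrides[name])
        channels[name] = ChannelModel(**kwargs)
    return channels


class SceneTruth(BaseModel):
    """Ground truth for one cell–bead conjugate scene.

    All coordinates are (z, y, x) in μm. The bead models the 3 μm latex
    beads used in antigen-coated bead assays (radius 1.5 μm) and must sit
    tangent/adjacent to the cell surface; nucleus and centrosome must lie
    inside the cell. ``polarity_true`` is *derived* from the geometry (the
    signed projection of the centrosome onto the cell-center→bead-center
    axis), so the truth is consistent with its own definition by
    construction.
    """

    seed: int = 0
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)
    shape: tuple[int, int, int] = (24, 100, 140)
    cell_center: tuple[float, float, float] = (6.0, 5.0, 5.0)
    cell_radius: float = Field(4.0, gt=0)
    nucleus_center: tuple[float, float, float] = (6.0, 5.0, 3.6)
    nucleus_radius: float = Field(2.2, gt=0)
    centrosome_pos: tuple[float, float, float] = (6.0, 5.0, 7.2)
    bead_center: tuple[float, float, float] = (6.0, 5.0, 10.5)
    bead_radius: float = Field(1.5, gt=0)
    extraction_fraction_true: float = Field(0.0, ge=0, le=1)
    lysosome_polarization_true: float = Field(0.5, ge=0, le=1)
    psf_sigma: float = Field(0.0, ge=0)
    channels: dict[str, ChannelModel] = Field(default_factory=default_channels)

    @field_validator("voxel_size")
    @classmethod
    def _positive_voxels(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("voxel_size entries must be strictly positive")
        return v

    @model_validator(mode="after")
    def _geometry(self):
        cc = np.array(self.cell_center)
        if (
            np.linalg.norm(np.array(self.nucleus_center) - cc) + self.nucleus_radius
            > self.cell_radius + 1e-9
        ):
            raise ValueError("nucleus_inside_cell: nucleus sphere must lie inside the cell sphere")
        if np.linalg.norm(np.array(self.centrosome_pos) - cc) >= self.cell_radius:
            raise ValueError("centrosome_inside_cell: centrosome must lie inside the cell sphere")
        gap = np.linalg.norm(np.array(self.bead_center) - cc) - (
            self.cell_radius + self.bead_radius
        )
        if abs(gap) > 0.5:
            raise ValueError(
                "bead_adjacent_to_cell: bead must be tangent/adjacent to the cell "
                f"surface (center offset from tangency: {gap:+.2f} μm)"
            )
        return self

    # -- derived geometry --------------------------------------------------

    @property
    def bead_axis(self) -> np.ndarray:
        """Unit vector from the cell center toward the bead center."""
        v = np.array(self.bead_center) - np.array(self.cell_center)
        return v / np.linalg.norm(v)

    @property
    def contact_point(self) -> np.ndarray:
        """Point where the cell surface meets the bead (μm)."""
        return np.array(self.cell_center) + self.cell_radius * self.bead_axis

    @property
    def polarity_true(self) -> float:
        """Signed projection of the centrosome on the cell→bead axis, normalized."""
        cc = np.array(self.cell_center)
        axis = np.array(self.bead_center) - cc
        return float(
            np.dot(np.array(self.centrosome_pos) - cc, axis) / np.dot(axis, axis)
        )

    @classmethod
    def with_polarity(
        cls,
        polarity: float,
        perpendicular_offset: float = 0.0,
        **kwargs,
    ) -> "SceneTruth":
        """Build a truth whose centrosome realizes the requested polarity.

        The centrosome is placed at ``cell_center + polarity · (bead_center −
        cell_center)``, optionally displaced perpendicular to the axis (which
        leaves the polarity unchanged). Polarities placing the centrosome
        outside the cell are rejected by the geometry validator.
        """
        base = cls(**kwargs)
        cc = np.array(base.cell_center)
        axis = np.array(base.bead_center) - cc
        # a unit vector perpendicular to the axis (any will do; pick stable one)
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, axis)) > 0.9 * np.linalg.norm(axis):
            trial = np.array([0.0, 1.0, 0.0])
        perp = np.cross(axis, trial)
        perp /= np.linalg.norm(perp)
        cent = cc + polarity * axis + perpendicular_offset * perp
        kwargs["centrosome_pos"] = tuple(cent)
        return cls(**kwargs)

    # -- sidecar -----------------------------------------------------------

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        return cls.model_validate_json(text)


# -- rendering -------------------------------------------------------------


def _grids(shape, spacing):
    z, y, x = voxel_centers(shape, spacing)
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _dist(grids, center):
    gz, gy, gx = grids
    cz, cy, cx = center
    return np.sqrt((gz - cz) ** 2 + (gy - cy) ** 2 + (gx - cx) ** 2)


def _sphere(grids, center, radius):
    return _dist(grids, center) <= radius


def _shell(grids, center, radius, thickness):
    return np.abs(_dist(grids, center) - radius) <= thickness / 2


def _add_gaussian_spot(out, truth, center, sigma, amplitude):
    """Add an isotropic (in μm) Gaussian spot, computed on a local window."""
    spacing = np.array(truth.voxel_size)
    shape = np.array(truth.shape)
    idx = np.array(center) / spacing - 0.5
    half = np.ceil(4 * sigma / spacing).astype(int) + 1
    lo = np.maximum(np.floor(idx).astype(int) - half, 0)
    hi = np.minimum(np.floor(idx).astype(int) + half + 1, shape)
    if np.any(lo >= hi):
        return
    axes = [
        ((np.arange(lo[k], hi[k]) + 0.5) * spacing[k] - center[k]) for k in range(3)
    ]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(
        -d2 / (2 * sigma**2)
    )


def _channel_rng(seed: int, name: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode()), salt])


def lysosome_positions(truth: SceneTruth, channel: ChannelModel) -> np.ndarray:
    """Sample lysosome punctum centers (μm) for the LAMP-1 channel.

    A fraction ``lysosome_polarization_true`` of puncta sits in the synaptic
    cap (near the cell–bead contact point, inside the fixed bead region), the
    rest uniformly in the cytoplasm outside the nucleus. Deterministic for a
    fixed truth (seeded sub-stream).
    """
    rng = _channel_rng(truth.seed, "lamp1")
    n = int(channel.param("n_puncta"))
    n_syn = int(round(truth.lysosome_polarization_true * n))
    cc = np.array(truth.cell_center)
    nc = np.array(truth.nucleus_center)
    bc = np.array(truth.bead_center)
    cap_sigma = channel.param("cap_sigma")
    contact = truth.contact_point
    positions = []
    while len(positions) < n_syn:
        pos = contact + rng.normal(0.0, cap_sigma, 3)
        if (
            np.linalg.norm(pos - cc) <= truth.cell_radius - 0.15
            and np.linalg.norm(pos - bc) <= truth.bead_radius + 0.4
        ):
            positions.append(pos)
    while len(positions) < n:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = cc + u * (truth.cell_radius - 0.15) * rng.uniform() ** (1 / 3)
        if np.linalg.norm(pos - nc) > truth.nucleus_radius:
            positions.append(pos)
    return np.array(positions)


def render_expectation(truth: SceneTruth, name: str) -> np.ndarray:
    """Noiseless expected intensity of one channel on the truth's voxel grid."""
    ch = truth.channels[name]
    grids = _grids(truth.shape, truth.voxel_size)
    out = np.full(truth.shape, float(ch.background))
    inside = _sphere(grids, truth.cell_center, truth.cell_radius)
    amp = ch.amplitude

    if name == "tubulin":
        out += amp * ch.param("haze_weight") * inside
        _add_gaussian_spot(out, truth, truth.centrosome_pos, ch.param("spot_sigma"), amp)
    elif name == "actin":
        out += amp * ch.param("cyto_weight") * inside
        out += (
            amp
            * ch.param("cortical_shell_weight")
            * _shell(grids, truth.cell_center, truth.cell_radius, ch.param("shell_thickness"))
        )
        w = ch.param("centrosomal_pool_weight")
        if w > 0:
            _add_gaussian_spot(
                out, truth, truth.centrosome_pos, ch.param("pool_sigma"), amp * w
            )
    elif name == "dapi":
        out += amp * _sphere(grids, truth.nucleus_center, truth.nucleus_radius)
    elif name == "lamp1":
        for pos in lysosome_positions(truth, ch):
            _add_gaussian_spot(out, truth, pos, ch.param("punctum_sigma"), amp)
    elif name == "ova":
        out += (
            amp
            * (1.0 - truth.extraction_fraction_true)
            * _shell(grids, truth.bead_center, truth.bead_radius, ch.param("shell_thickness"))
        )
    elif name == "proteasome":
        w = ch.param("centrosomal_pool_weight")
        if w > 0:
            _add_gaussian_spot(
                out, truth, truth.centrosome_pos, ch.param("pool_sigma"), amp * w
            )
        out += (
            amp
            * ch.param("cortical_shell_weight")
            * _shell(grids, truth.cell_center, truth.cell_radius, ch.param("shell_thickness"))
        )
    elif name == "psyk":
        _add_gaussian_spot(out, truth, tuple(truth.contact_point), ch.param("cluster_sigma"), amp)
    else:
        raise ValueError(f"no volume renderer for channel {name!r}")

    if truth.psf_sigma > 0:
        out = gaussian_filter(out, sigma=np.array(truth.psf_sigma) / np.array(truth.voxel_size))
    return out


def _apply_noise(expectation: np.ndarray, ch: ChannelModel, rng: np.random.Generator):
    out = expectation
    if ch.photon_scale is not None and np.isfinite(ch.photon_scale):
        out = rng.poisson(ch.photon_scale * expectation).astype(np.float64) / ch.photon_scale
    if ch.read_sigma > 0:
        out = out + rng.normal(0.0, ch.read_sigma, out.shape)
    return np.clip(out, 0.0, None)


def generate_conjugate(truth: SceneTruth) -> ImageStack:
    """Render a multi-channel 3-D conjugate stack from its ground truth.

    Channel order follows ``truth.channels``. Deterministic for a fixed
    truth: structure randomness (lysosome positions) and camera noise both
    derive from ``truth.seed``.
    """
    noise_rng = _channel_rng(truth.seed, "camera-noise")
    planes = []
    for name, ch in truth.channels.items():
        exp = render_expectation(truth, name)
        planes.append(_apply_noise(exp, ch, noise_rng).astype(np.float32))
    return ImageStack(
        data=np.stack(planes),
        spacing=truth.voxel_size,
        channel_names=tuple(truth.channels),
        kind=VOLUME,
    )


def write_scene(stack: ImageStack, truth: SceneTruth, outdir: str | Path, stem: str | None = None):
    """Write a stack and its truth sidecar, paired by shared filename stem."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"scene_{truth.seed:08d}"
    tiff = write_stack(stack, outdir / f"{stem}.tif")
    (outdir / f"{stem}.json").write_text(truth.to_json())
    return tiff, outdir / f"{stem}.json"


def read_truth_sidecar(stack_path: str | Path) -> SceneTruth:
    """Load the truth sidecar paired with a stack path (shared stem)."""
    path = Path(stack_path).with_suffix(".json")
    return SceneTruth.from_json(path.read_text())


# -- spreading time-lapses --------------------------------------------------


class SpreadingTruth(BaseModel):
    """Ground truth for a 2-D spreading time-lapse.

    The footprint is a disk whose area follows
    ``A(t) = A0 + (A_max − A0)(1 − e^(−t/τ))`` (μm², monotone
    non-decreasing). ``ring_fraction`` of the total fluorescence sits in the
    peripheral ring outside the concentric one-third-area disk, emulating
    the peripheral actin ring of a spreading lymphocyte; total fluorescence
    is conserved over time. Default frame interval 15 s matches typical
    TIRF spreading acquisitions; 10 s framing for kymograph-style movies is
    supported by overriding it.
    """

    seed: int = 0
    frame_interval: float = Field(15.0, gt=0)
    duration: float = Field(600.0, gt=0)
    A0: float = Field(30.0, gt=0)
    A_max: float = Field(120.0, gt=0)
    tau: float = Field(120.0, gt=0)
    ring_fraction: float = Field(0.75, ge=0, le=1)
    pixel_size: float = Field(0.1, gt=0)
    shape: tuple[int, int] = (180, 180)
    center: tuple[float, float] | None = None
    background: float = Field(2.0, ge=0)
    total_flux: float = Field(50000.0, gt=0)
    photon_scale: float | None = Field(None, gt=0)
    read_sigma: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _curve(self):
        if self.A_max < self.A0:
            raise ValueError("area_curve_monotone: A_max must be >= A0")
        r_max = np.sqrt(self.A_max / np.pi)
        extent = min(self.shape) * self.pixel_size
        if 2 * r_max > extent:
            raise ValueError(
                f"field_of_view: footprint diameter {2 * r_max:.1f} μm exceeds "
                f"the {extent:.1f} μm field"
            )
        return self

    def area(self, t) -> np.ndarray:
        """Analytic footprint area A(t), μm²."""
        t = np.asarray(t, dtype=float)
        return self.A0 + (self.A_max - self.A0) * (1.0 - np.exp(-t / self.tau))

    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpreadingTruth":
        return cls.model_validate_json(text)


def generate_spreading(truth: SpreadingTruth) -> ImageStack:
    """Render a LifeAct-like spreading time-lapse from its ground truth."""
    ny, nx = truth.shape
    cy, cx = truth.center or ((ny * truth.pixel_size) / 2, (nx * truth.pixel_size) / 2)
    y = (np.arange(ny) + 0.5) * truth.pixel_size
    x = (np.arange(nx) + 0.5) * truth.pixel_size
    rr = np.sqrt((y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2)
    rng = _channel_rng(truth.seed, "lifeact")
    px_area = truth.pixel_size**2
    frames = []
    for t in truth.times():
        area = float(truth.area(t))
        r = np.sqrt(area / np.pi)
        r_in = r * np.sqrt(1.0 / 3.0)
        inner = rr <= r_in
        ring = (rr > r_in) & (rr <= r)
        a_c = area / 3.0
        a_r = area - a_c
        frame = np.full((ny, nx), float(truth.background))
        frame += inner * (truth.total_flux * (1 - truth.ring_fraction) / a_c * px_area)
        frame += ring * (truth.total_flux * truth.ring_fraction / a_r * px_area)
        if truth.photon_scale is not None and np.isfinite(truth.photon_scale):
            frame = rng.poisson(truth.photon_scale * frame) / truth.photon_scale
        if truth.read_sigma > 0:
            frame = frame + rng.normal(0.0, truth.read_sigma, frame.shape)
        frames.append(np.clip(frame, 0.0, None).astype(np.float32))
    return ImageStack(
        data=np.stack(frames),
        spacing=(truth.pixel_size, truth.pixel_size),
        frame_interval=truth.frame_interval,
        kind=TIMELAPSE,
    )


def write_spreading_scene(
    stack: ImageStack, truth: SpreadingTruth, outdir: str | Path, stem: str | None = None
):
    """Write a time-lapse and its truth sidecar, paired by shared stem."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"movie_{truth.seed:08d}"
    tiff = write_stack(stack, outdir / f"{stem}.tif")
    (outdir / f"{stem}.json").write_text(truth.to_json())
    return tiff, outdir / f"{stem}.json"


# -- truth samplers ---------------------------------------------------------


def sample_conjugate_truth(
    seed: int,
    polarity_range: tuple[float, float] = (-0.6, 0.6),
    extraction_range: tuple[float, float] = (0.0, 0.8),
    lysosome_range: tuple[float, float] = (0.1, 0.9),
    snr: float | None = None,
    channel_overrides: dict[str, dict] | None = None,
    **truth_kwargs,
) -> SceneTruth:
    """Draw a random conjugate truth for recovery experiments.

    Polarity is sampled within the physically attainable range (the
    centrosome must stay inside the cell), with a random displacement
    perpendicular to the cell→bead axis.
    """
    rng = np.random.default_rng(seed)
    polarity = rng.uniform(*polarity_range)
    truth_kwargs.setdefault("extraction_fraction_true", float(rng.uniform(*extraction_range)))
    truth_kwargs.setdefault("lysosome_polarization_true", float(rng.uniform(*lysosome_range)))
    truth_kwargs.setdefault("channels", default_channels(snr=snr, overrides=channel_overrides))
    perp = float(rng.uniform(0.0, 1.0))
    return SceneTruth.with_polarity(
        polarity, perpendicular_offset=perp, seed=seed, **truth_kwargs
    )
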