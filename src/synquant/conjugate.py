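"""Per-cell indices for B cell–bead conjugates.

Implements the geometric and fluorometric readouts of centrosome
polarization and cargo delivery at the immune synapse:

* ``polarity_index`` — signed projection of the centrosome (Cent) onto the
  cell-mass-center→bead-mass-center (CMC→BMC) axis, normalized by the axis
  length: +1 fully polarized (Cent at BMC), 0 at the cell center, −1
  anti-polarized.
* ``centrosome_nucleus_distance`` — Euclidean μm distance Cent↔MCN.
* ``density_index`` — fluorescence density in a 1 μm radius region at the
  centrosome (DCent = FCent/ACent) divided by the whole-cell density
  (DCell); > 1 means accumulation at the centrosome, < 1 depletion.
* ``recruitment_pct`` — % of cellular fluorescence inside the fixed bead
  region (e.g. LAMP-1 lysosome recruitment, proteasome recruitment).
* ``extraction_pct`` — % of antigen fluorescence lost by beads relative to a
  reference bead population, measured on z-sum projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedAxisError, UndefinedRatioError
from .segmentation import BeadRegion, ConjugateSegmentation
from .stack import ImageStack, sum_projection

__all__ = [
    "polarity_index",
    "centrosome_nucleus_distance",
    "density_index",
    "recruitment_pct",
    "extraction_pct",
    "bead_total_fluorescence",
    "ExtractionResult",
    "ConjugateReport",
    "measure_conjugate",
]

#: |index| beyond which a polarity value is flagged (centrosome projecting
#: beyond the bead or behind the anti-pole); values are reported unclamped.
POLARITY_FLAG_RANGE = 1.0


def polarity_index(cent, cmc, bmc) -> float:
    """Centrosome polarity index.

    The centrosome position is projected onto the vector from the cell mass
    center (CMC) to the bead mass center (BMC); the index is the signed
    distance CMC→projection divided by the distance CMC→BMC. Positive values
    point toward the bead. Values are *not* clamped to [−1, 1]; use
    :func:`polarity_out_of_range` to flag them.

    Raises
    ------
    UndefinedAxisError
        If CMC and BMC coincide (no axis).
    """
    cent = np.asarray(cent, dtype=float)
    cmc = np.asarray(cmc, dtype=float)
    bmc = np.asarray(bmc, dtype=float)
    axis = bmc - cmc
    norm2 = float(np.dot(axis, axis))
    if norm2 == 0.0:
        raise UndefinedAxisError("CMC and BMC coincide; polarity axis undefined")
    return float(np.dot(cent - cmc, axis) / norm2)


def polarity_out_of_range(index: float) -> bool:
    """True when a polarity index falls outside the nominal [−1, +1] range."""
    return abs(index) > POLARITY_FLAG_RANGE


def centrosome_nucleus_distance(cent, mcn) -> float:
    """Euclidean distance between centrosome and nucleus mass center, μm.

    Both landmarks must already be physical coordinates, so anisotropic
    voxel spacing is respected by construction.
    """
    return float(np.linalg.norm(np.asarray(cent, float) - np.asarray(mcn, float)))


def density_index(
    stack: ImageStack,
    channel: str,
    cent,
    cell_mask: np.ndarray,
    radius: float = 1.0,
    mode: str = "slice",
) -> float:
    """Centrosomal fluorescence density index DCent/DCell.

    ``mode="slice"`` (default) quantifies a 1 μm radius *circle* in the
    z-plane nearest the centrosome, matching single-plane practice; both
    DCent and DCell are computed in that plane. ``mode="sphere"`` uses the
    full 3-D sphere and the whole 3-D cell mask. Either way both densities
    share units, so the index is dimensionless; uniform fluorescence gives
    exactly 1.
    """
    cell_mask = np.asarray(cell_mask, bool)
    img = np.asarray(stack.channel(channel), dtype=float)
    cent = np.asarray(cent, dtype=float)
    spacing = np.asarray(stack.spacing)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(img.shape, spacing)]

    if mode == "slice":
        iz = int(np.clip(np.round(cent[0] / spacing[0] - 0.5), 0, img.shape[0] - 1))
        plane = img[iz]
        plane_mask = cell_mask[iz]
        d2 = (coords[1][:, None] - cent[1]) ** 2 + (coords[2][None, :] - cent[2]) ** 2
        cent_region = (d2 <= radius**2) & plane_mask
        cell_region = plane_mask
        values = plane
    elif mode == "sphere":
        d2 = (
            (coords[0][:, None, None] - cent[0]) ** 2
            + (coords[1][None, :, None] - cent[1]) ** 2
            + (coords[2][None, None, :] - cent[2]) ** 2
        )
        cent_region = (d2 <= radius**2) & cell_mask
        cell_region = cell_mask
        values = img
    else:
        raise ValueError(f"mode must be 'slice' or 'sphere', got {mode!r}")

    if not cent_region.any():
        raise UndefinedRatioError(
            "centrosomal region empty after intersection with the cell mask"
        )
    if not cell_region.any():
        raise UndefinedRatioError("cell mask empty in the quantification plane")
    d_cent = values[cent_region].sum() / cent_region.sum()
    d_cell = values[cell_region].sum() / cell_region.sum()
    if d_cell == 0:
        raise UndefinedRatioError("whole-cell fluorescence is zero")
    return float(d_cent / d_cell)


def recruitment_pct(
    stack: ImageStack,
    channel: str,
    bead_region: np.ndarray | BeadRegion,
    cell_mask: np.ndarray,
) -> float:
    """Percent of cellular fluorescence located at the bead.

    100 · F(bead region) / F(cell mask ∪ bead region). Including the bead
    region in the denominator makes the metric a true fraction bounded by
    [0, 100].
    """
    if isinstance(bead_region, BeadRegion):
        bead_region = bead_region.mask
    bead_region = np.asarray(bead_region, bool)
    cell_mask = np.asarray(cell_mask, bool)
    img = np.asarray(stack.channel(channel), dtype=float)
    total = img[cell_mask | bead_region].sum()
    if total <= 0:
        raise UndefinedRatioError("total fluorescence over cell ∪ bead region is zero")
    return float(100.0 * img[bead_region].sum() / total)


def bead_total_fluorescence(
    stack: ImageStack,
    channel: str,
    bead_region: np.ndarray | BeadRegion,
    background: float = 0.0,
) -> float:
    """Total bead fluorescence on the z-sum projection of the fixed region.

    The projection conserves intensity, so this equals the 3-D total over
    the region; it is computed through the projection to mirror the
    sum-slices measurement convention. ``background`` (per-voxel, optional)
    is subtracted times the region volume; no subtraction by default.
    """
    if isinstance(bead_region, BeadRegion):
        bead_region = bead_region.mask
    bead_region = np.asarray(bead_region, bool)
    proj = sum_projection(np.asarray(stack.channel(channel), float), bead_region)
    return float(proj.sum() - background * bead_region.sum())


@dataclass
class ExtractionResult:
    """Antigen-extraction summary for a bead population."""

    per_bead_pct: np.ndarray
    mean_pct: float
    sem_pct: float
    reference_mean: float


def extraction_pct(bead_fluorescences, reference_fluorescences) -> ExtractionResult:
    """Percent of antigen fluorescence lost by beads vs a reference population.

    Per bead: 100 · (1 − F_bead / mean(F_reference)). The reference is the
    bead population before extraction (time 0 or non-activating ligand),
    since fixed-cell assays have no per-bead before/after pairing. Values
    are not clamped (noise can produce slightly negative losses).
    """
    bead = np.asarray(bead_fluorescences, dtype=float)
    ref = np.asarray(reference_fluorescences, dtype=float)
    if ref.size == 0 or ref.mean() <= 0:
        raise UndefinedRatioError("reference bead population empty or non-positive mean")
    per = 100.0 * (1.0 - bead / ref.mean())
    sem = float(per.std(ddof=1) / np.sqrt(per.size)) if per.size > 1 else 0.0
    return ExtractionResult(
        per_bead_pct=per,
        mean_pct=float(per.mean()),
        sem_pct=sem,
        reference_mean=float(ref.mean()),
    )


@dataclass
class ConjugateReport:
    """All conjugate indices for one cell–bead pair."""

    polarity_index: float
    polarity_flagged: bool
    centrosome_nucleus_distance: float
    density_index: dict[str, float] = field(default_factory=dict)
    recruitment_pct: dict[str, float] = field(default_factory=dict)
    bead_fluorescence: dict[str, float] = field(default_factory=dict)
    extraction_pct: float | None = None
    condition: str = ""
    time_label: str = ""

    def as_row(self) -> dict:
        row = {
            "condition": self.condition,
            "time_label": self.time_label,
            "polarity_index": self.polarity_index,
            "polarity_flagged": self.polarity_flagged,
            "centrosome_nucleus_distance_um": self.centrosome_nucleus_distance,
            "extraction_pct": self.extraction_pct,
        }
        for name, v in self.density_index.items():
            row[f"density_index_{name}"] = v
        for name, v in self.recruitment_pct.items():
            row[f"recruitment_pct_{name}"] = v
        for name, v in self.bead_fluorescence.items():
            row[f"bead_fluorescence_{name}"] = v
        return row


def measure_conjugate(
    stack: ImageStack,
    seg: ConjugateSegmentation,
    density_channels: tuple[str, ...] = ("actin",),
    recruitment_channels: tuple[str, ...] = ("lamp1",),
    bead_channels: tuple[str, ...] = ("ova",),
    density_radius: float = 1.0,
    density_mode: str = "slice",
    bead_background: float = 0.0,
    condition: str = "",
    time_label: str = "",
) -> ConjugateReport:
    """Compute every conjugate index for one segmented stack.

    ``bead_channels`` totals are fluorescence sums over the fixed bead
    region (optionally minus a per-voxel ``bead_background``); extraction %
    is filled in later at the population level (it needs the reference bead
    mean).
    """
    p = polarity_index(seg.centrosome, seg.cell_mass_center, seg.bead_mass_center)
    report = ConjugateReport(
        polarity_index=p,
        polarity_flagged=polarity_out_of_range(p),
        centrosome_nucleus_distance=centrosome_nucleus_distance(
            seg.centrosome, seg.nucleus_mass_center
        ),
        condition=condition,
        time_label=time_label,
    )
    for name in density_channels:
        report.density_index[name] = density_index(
            stack, name, seg.centrosome, seg.cell_mask, radius=density_radius, mode=density_mode
        )
    for name in recruitment_channels:
        report.recruitment_pct[name] = recruitment_pct(
            stack, name, seg.bead_region, seg.cell_mask
        )
    for name in bead_channels:
        report.bead_fluorescence[name] = bead_total_fluorescence(
            stack, name, seg.bead_region, background=bead_background
        )
    return report
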