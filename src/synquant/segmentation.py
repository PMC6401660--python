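"""Masks and landmarks for conjugate stacks.

The paper-era workflow outlined cells manually on the phalloidin channel;
here a single documented rule replaces it and is shared by the 3-D and 2-D
paths: Gaussian smoothing (σ = 1 px per axis by default), Otsu threshold,
keep the connected component containing the brightest smoothed voxel, fill
holes. All landmark outputs are physical μm coordinates (voxel-center
convention); mass centers are binary-mask centroids by default with an
intensity-weighted option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import AmbiguityError, SegmentationError
from .stack import ImageStack, index_to_physical

__all__ = [
    "ConjugateSegmentation",
    "BeadRegion",
    "segment_cell",
    "segment_plane",
    "locate_centrosome",
    "define_bead_region",
    "mask_centroid",
]


def mask_centroid(mask: np.ndarray, spacing, weights: np.ndarray | None = None) -> np.ndarray:
    """Centroid of a mask in physical μm coordinates.

    Binary centroid by default; pass ``weights`` (an intensity array of the
    same shape) for an intensity-weighted mass center.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise SegmentationError("cannot take the centroid of an empty mask")
    idx = np.argwhere(mask).astype(float)
    if weights is not None:
        w = np.asarray(weights, dtype=float)[mask]
        if w.sum() <= 0:
            raise SegmentationError("centroid weights sum to zero")
        center = (idx * w[:, None]).sum(axis=0) / w.sum()
    else:
        center = idx.mean(axis=0)
    return index_to_physical(center, spacing)


def _threshold_mask(image: np.ndarray, sigma) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared smoothing + Otsu + brightest-seeded-component rule."""
    image = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, sigma=sigma)
    if smoothed.max() == smoothed.min():
        raise SegmentationError(
            "channel has zero dynamic range; nothing to segment", threshold=None
        )
    threshold = float(threshold_otsu(smoothed))
    binary = smoothed > threshold
    if not binary.any():
        raise SegmentationError(
            f"empty mask after thresholding at {threshold:g}", threshold=threshold
        )
    labels, _ = ndimage.label(binary)
    seed = np.unravel_index(np.argmax(smoothed), smoothed.shape)
    seed_label = labels[seed]
    if seed_label == 0:  # brightest voxel below threshold cannot happen post-Otsu,
        # but guard against pathological inputs
        raise SegmentationError(
            f"global maximum not inside any component at threshold {threshold:g}",
            threshold=threshold,
        )
    mask = labels == seed_label
    mask = ndimage.binary_fill_holes(mask)
    return mask, smoothed, threshold


def segment_cell(
    stack: ImageStack,
    channel: str,
    sigma: float = 1.0,
    exclude_bead: np.ndarray | None = None,
) -> np.ndarray:
    """Segment the cell body from a structural channel (e.g. F-actin).

    Returns a single connected boolean volume containing the global maximum
    of the smoothed channel. If ``exclude_bead`` is given, that region is
    removed from the mask (a documented switch: whether the cell outline
    should include the bead contact arc is an analysis choice).
    """
    mask, _, _ = _threshold_mask(stack.channel(channel), sigma)
    if exclude_bead is not None:
        mask = mask & ~np.asarray(exclude_bead, bool)
        if not mask.any():
            raise SegmentationError("cell mask empty after bead exclusion")
    return mask


def segment_plane(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """2-D footprint segmentation with the same rule as :func:`segment_cell`."""
    mask, _, _ = _threshold_mask(image, sigma)
    return mask


def locate_centrosome(
    stack: ImageStack,
    channel: str,
    cell_mask: np.ndarray,
    sigma: float = 1.0,
) -> np.ndarray:
    """Centrosome position: the brightest point of the smoothed tubulin channel.

    The maximum is taken over ``cell_mask`` only. Ties resolve to the lowest
    (z, y, x) index in scan order. Returns μm coordinates.
    """
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        raise SegmentationError("cell mask is empty")
    smoothed = ndimage.gaussian_filter(np.asarray(stack.channel(channel), float), sigma)
    inside = smoothed[cell_mask]
    if inside.max() == inside.min():
        raise AmbiguityError(
            "tubulin channel is flat inside the cell mask; centrosome undefined"
        )
    masked = np.where(cell_mask, smoothed, -np.inf)
    # np.argmax returns the first maximum in C scan order == lowest (z, y, x)
    idx = np.unravel_index(np.argmax(masked), masked.shape)
    return index_to_physical(idx, stack.spacing)


@dataclass
class BeadRegion:
    """A fixed spherical quantification region around one bead.

    ``clipped`` flags beads whose region extends beyond the field of view.
    """

    mask: np.ndarray
    center: tuple[float, float, float]
    radius: float
    clipped: bool


def define_bead_region(
    stack: ImageStack,
    bead_center,
    bead_radius: float,
    margin: float = 0.5,
) -> BeadRegion:
    """Fixed-size spherical region of radius ``bead_radius + margin`` (μm).

    The same margin must be used for every bead of a batch so that bead
    fluorescence totals are comparable (the fixed-area contract).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    radius = bead_radius + margin
    center = np.asarray(bead_center, dtype=float)
    shape = stack.spatial_shape
    spacing = stack.spacing
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    d2 = (
        (coords[0][:, None, None] - center[0]) ** 2
        + (coords[1][None, :, None] - center[1]) ** 2
        + (coords[2][None, None, :] - center[2]) ** 2
    )
    mask = d2 <= radius**2
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    clipped = bool(np.any(center - radius < 0) or np.any(center + radius > extent))
    return BeadRegion(mask=mask, center=tuple(center), radius=radius, clipped=clipped)


@dataclass
class ConjugateSegmentation:
    """All masks and landmarks needed by the conjugate metrics.

    Landmarks (μm, (z, y, x)): ``centrosome`` (Cent), ``cell_mass_center``
    (CMC), ``bead_mass_center`` (BMC), ``nucleus_mass_center`` (MCN). Mass
    centers equal the centroids of their stored masks and are recomputable
    from them.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    bead_region: BeadRegion
    centrosome: np.ndarray
    cell_mass_center: np.ndarray
    bead_mass_center: np.ndarray
    nucleus_mass_center: np.ndarray

    @classmethod
    def from_stack(
        cls,
        stack: ImageStack,
        bead_center,
        bead_radius: float,
        cell_channel: str = "actin",
        nucleus_channel: str = "dapi",
        tubulin_channel: str = "tubulin",
        bead_margin: float = 0.5,
        sigma: float = 1.0,
        exclude_bead: bool = False,
    ) -> "ConjugateSegmentation":
        """Segment a conjugate stack given known bead geometry.

        Bead geometry comes from a truth sidecar, a bead channel fit, or a
        manual annotation — the spherical quantification region is then fixed
        across the batch.
        """
        bead = define_bead_region(stack, bead_center, bead_radius, bead_margin)
        cell_mask = segment_cell(
            stack, cell_channel, sigma=sigma, exclude_bead=bead.mask if exclude_bead else None
        )
        nucleus_mask = segment_cell(stack, nucleus_channel, sigma=sigma)
        cent = locate_centrosome(stack, tubulin_channel, cell_mask, sigma=sigma)
        return cls(
            cell_mask=cell_mask,
            nucleus_mask=nucleus_mask,
            bead_region=bead,
            centrosome=cent,
            cell_mass_center=mask_centroid(cell_mask, stack.spacing),
            bead_mass_center=mask_centroid(bead.mask, stack.spacing),
            nucleus_mass_center=mask_centroid(nucleus_mask, stack.spacing),
        )
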