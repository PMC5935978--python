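"""3D CT-number quantification of a segmented lung nodule.

The measurement proceeds in three steps: (a) segment the nodule from the
surrounding lung, (b) obtain component HU thresholds from appearance-labeled
tumors by ROC analysis (see :mod:`nodulequant.thresholding`), and (c) build the
nodule's CT-number histogram and compute the ground-glass component (GGOc) and
solid component (Sc) proportions as the fraction of mask voxels at or below /
at or above the respective thresholds.

HU values are treated as integers (CT reconstructions produce integer HU), so
the histogram uses 1-HU-wide, half-open, integer-aligned bins and the
conventional half-integer thresholds (e.g. -411.5 HU) can never tie with a
voxel value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "NoduleMask",
    "HUHistogram",
    "ComponentProportions",
    "MeanCT",
    "EmptySegmentationError",
    "MaskEditError",
    "segment_nodule",
    "edit_mask",
    "mean_ct",
    "hu_histogram",
    "component_proportions",
]

HU_MIN = -1024
HU_MAX = 3071

#: Default GGOc / Sc thresholds (HU).
T_GGO_DEFAULT = -411.5
T_SC_DEFAULT = -189.5


class EmptySegmentationError(ValueError):
    """Raised when segmentation or a mask edit produces an empty mask."""


class MaskEditError(ValueError):
    """Raised when a mask edit empties or disconnects the mask."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of Hounsfield-unit voxels with physical geometry.

    Parameters
    ----------
    voxels : ndarray of int, shape (nx, ny, nz)
        HU values, within [-1024, 3071].
    spacing_mm : tuple of float
        Physical edge length of a voxel along each axis.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {vox.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if vox.min() < HU_MIN or vox.max() > HU_MAX:
            raise ValueError(
                f"HU out of range [{HU_MIN}, {HU_MAX}]: "
                f"[{vox.min()}, {vox.max()}]"
            )
        object.__setattr__(self, "voxels", vox)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass(frozen=True)
class NoduleMask:
    """Binary voxel support of a segmented nodule.

    ``connectivity`` states the neighborhood convention under which the mask is
    a single connected component (3 means 26-neighborhood). ``touches_border``
    flags masks that reached the volume boundary during segmentation; such
    masks may be truncated.
    """

    support: np.ndarray
    connectivity: int = 3
    touches_border: bool = False

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=bool)
        if sup.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {sup.shape}")
        if not sup.any():
            raise EmptySegmentationError("mask is empty")
        object.__setattr__(self, "support", sup)

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())

    def is_connected(self) -> bool:
        structure = ndimage.generate_binary_structure(3, self.connectivity)
        _, n = ndimage.label(self.support, structure=structure)
        return n == 1


class MeanCT(NamedTuple):
    """Mean, minimum and maximum HU over a mask."""

    mean: float
    min: int
    max: int


@dataclass(frozen=True)
class HUHistogram:
    """Per-HU-bin voxel counts inside a nodule mask.

    Bins are half-open ``[bin_edges[i], bin_edges[i+1])`` with integer,
    strictly increasing edges; ``sum(counts) == total`` always.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges)
        counts = np.asarray(self.counts)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("negative bin count")
        if int(counts.sum()) != self.total:
            raise ValueError(
                f"counts sum to {int(counts.sum())}, expected total={self.total}"
            )
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ComponentProportions:
    """GGOc / Sc proportions of a nodule (percent of mask voxels).

    ``ggoc_prop`` is the percentage of voxels with HU <= ``t_ggo``; ``sc_prop``
    the percentage with HU >= ``t_sc``. Voxels strictly between the thresholds
    belong to neither component.
    """

    ggoc_prop: float
    sc_prop: float
    t_ggo: float
    t_sc: float


def _physical_distance_grid(
    shape: tuple[int, ...],
    seed_point: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    axes = [
        (np.arange(n) - s) * sp
        for n, s, sp in zip(shape, seed_point, spacing_mm)
    ]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(dx**2 + dy**2 + dz**2)


def segment_nodule(
    volume: CTVolume,
    seed_point: tuple[int, int, int],
    hu_floor: float = -750.0,
    max_radius_mm: float = 25.0,
    closing_radius_vox: int = 1,
) -> NoduleMask:
    """Segment a nodule by seeded region growing with an HU floor.

    The region is grown from ``seed_point`` over 26-connected voxels with
    HU > ``hu_floor``, limited to ``max_radius_mm`` (physical distance) from
    the seed, then regularized by morphological closing with a ball structuring
    element. The radius cap plus subsequent manual editing (:func:`edit_mask`)
    stand in for the inspect-and-edit loop used with clinical auto-contour
    software; juxta-vascular structures are excluded heuristically, not
    anatomically.

    Raises
    ------
    EmptySegmentationError
        If the seed voxel itself is at or below ``hu_floor``.
    """
    shape = volume.shape
    seed_point = tuple(int(i) for i in seed_point)
    if any(not (0 <= i < n) for i, n in zip(seed_point, shape)):
        raise ValueError(f"seed point {seed_point} outside volume {shape}")
    if volume.voxels[seed_point] <= hu_floor:
        raise EmptySegmentationError(
            f"seed voxel HU {volume.voxels[seed_point]} is not above the "
            f"floor {hu_floor}; nothing to grow"
        )

    dist = _physical_distance_grid(shape, seed_point, volume.spacing_mm)
    candidate = (volume.voxels > hu_floor) & (dist <= max_radius_mm)

    structure = ndimage.generate_binary_structure(3, 3)  # 26-neighborhood
    labels, _ = ndimage.label(candidate, structure=structure)
    region = labels == labels[seed_point]

    # flag border contact on the grown region, before closing can erode it
    touches = bool(
        region[0].any() or region[-1].any()
        or region[:, 0].any() or region[:, -1].any()
        or region[:, :, 0].any() or region[:, :, -1].any()
    )

    if closing_radius_vox > 0:
        ball = _ball_structure(closing_radius_vox)
        region = ndimage.binary_closing(region, structure=ball)
        region &= dist <= max_radius_mm
        # closing can strand voxels; keep the seed's component
        labels, _ = ndimage.label(region, structure=structure)
        region = labels == labels[seed_point]

    if touches:
        warnings.warn(
            "segmented region touches the volume border; mask may be truncated",
            stacklevel=2,
        )
    return NoduleMask(support=region, connectivity=3, touches_border=touches)


def _ball_structure(radius: int) -> np.ndarray:
    r = int(radius)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (grid**2).sum(axis=0) <= r**2


def edit_mask(
    mask: NoduleMask,
    include: set[tuple[int, int, int]] | None = None,
    exclude: set[tuple[int, int, int]] | None = None,
) -> NoduleMask:
    """Apply a radiologist's manual contour edit to a mask.

    ``include`` voxels are added, ``exclude`` voxels removed (exclusion wins on
    overlap, mirroring erasure of a wrongly included structure). The result
    must remain non-empty and a single connected component under the mask's
    connectivity convention.
    """
    include = include or set()
    exclude = exclude or set()
    shape = mask.support.shape
    for vox in list(include) + list(exclude):
        if any(not (0 <= i < n) for i, n in zip(vox, shape)):
            raise ValueError(f"edit voxel {vox} outside grid {shape}")

    new = mask.support.copy()
    for vox in include:
        new[tuple(vox)] = True
    for vox in exclude:
        new[tuple(vox)] = False

    if not new.any():
        raise MaskEditError("edit would empty the mask")
    edited = replace(mask, support=new)
    if not edited.is_connected():
        raise MaskEditError("edit would disconnect the mask")
    return edited


def _masked_values(volume: CTVolume, mask: NoduleMask) -> np.ndarray:
    if volume.shape != mask.support.shape:
        raise ValueError(
            f"volume {volume.shape} and mask {mask.support.shape} are not congruent"
        )
    return volume.voxels[mask.support]


def mean_ct(volume: CTVolume, mask: NoduleMask) -> MeanCT:
    """Mean CT value over the mask, with the HU range.

    This is the per-tumor statistic tallied after segmentation and the default
    predictor for threshold derivation.
    """
    vals = _masked_values(volume, mask)
    return MeanCT(float(vals.mean()), int(vals.min()), int(vals.max()))


def hu_histogram(volume: CTVolume, mask: NoduleMask, bin_width: int = 1) -> HUHistogram:
    """CT-number histogram of the mask voxels.

    Bins are ``bin_width``-HU wide, half-open and aligned to integer multiples
    of ``bin_width``, so every voxel falls in exactly one bin and the counts
    sum to the mask size.
    """
    if bin_width < 1 or int(bin_width) != bin_width:
        raise ValueError(f"bin width must be a positive integer, got {bin_width}")
    vals = _masked_values(volume, mask).astype(np.int64)
    w = int(bin_width)
    lo = (vals.min() // w) * w
    hi = (vals.max() // w) * w + w
    edges = np.arange(lo, hi + w, w)
    idx = (vals - lo) // w
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return HUHistogram(bin_edges=edges, counts=counts, total=int(vals.size))


def component_proportions(
    hist: HUHistogram,
    t_ggo: float = T_GGO_DEFAULT,
    t_sc: float = T_SC_DEFAULT,
) -> ComponentProportions:
    """GGOc and Sc proportions from a CT-number histogram.

    GGOc collects the mass at or below ``t_ggo``; Sc the mass at or above
    ``t_sc``. A bin that straddles a threshold cannot be attributed and raises;
    with the default 1-HU integer bins and half-integer thresholds this never
    happens.
    """
    if t_ggo >= t_sc:
        raise ValueError(f"need t_ggo < t_sc, got {t_ggo} >= {t_sc}")
    if hist.total == 0:
        raise ValueError("empty histogram")

    lo = hist.bin_edges[:-1].astype(float)
    hi = hist.bin_edges[1:].astype(float)
    # a bin is wholly ggoc iff every representable value in [lo, hi) is <= t_ggo;
    # HU are integers so the largest value in the bin is hi - 1
    ggo_bins = (hi - 1) <= t_ggo
    sc_bins = lo >= t_sc
    straddle_ggo = (lo <= t_ggo) & ((hi - 1) > t_ggo)
    straddle_sc = (lo < t_sc) & ((hi - 1) >= t_sc)
    if ((straddle_ggo | straddle_sc) & (hist.counts > 0)).any():
        raise ValueError(
            "a non-empty histogram bin straddles a component threshold; "
            "use 1-HU bins or threshold on a bin edge"
        )
    ggoc = float(hist.counts[ggo_bins].sum()) / hist.total * 100.0
    sc = float(hist.counts[sc_bins].sum()) / hist.total * 100.0
    return ComponentProportions(ggoc_prop=ggoc, sc_prop=sc, t_ggo=t_ggo, t_sc=t_sc)
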