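"""Patient-specific occlusion-downstream region construction.

The downstream area of an occluded artery is approximated by the hypoperfused
tissue on the CT perfusion Tmax map (strictly above 6 s by default).  Because
perfusion software carves vessels out of its maps, the thresholded mask has
vessel-shaped tunnels; these are filled by morphological closing with a 3D
ellipsoidal structuring element (default semi-axes 10, 10, 1 voxels in x, y,
z), so that vessels penetrating the downstream area become part of the
refined mask.  The refined mask is mirrored across the midline plane to
obtain the contralateral comparison region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, NoHypoperfusionError
from .geometry import MidlinePlane, mirror_mask
from .imaging_io import BinaryMask, ImageVolume

DEFAULT_TMAX_THRESHOLD_S = 6.0
DEFAULT_SEMI_AXES = (10, 10, 1)


@dataclass(frozen=True)
class ClosingParams:
    """Ellipsoidal structuring element, semi-axes in voxel units (x, y, z).

    A semi-axis of 0 restricts that axis to offset 0; (0, 0, 0) degenerates
    to the single origin voxel, making closing the identity.
    """

    semi_axes_voxels: tuple[int, int, int] = DEFAULT_SEMI_AXES

    def __post_init__(self) -> None:
        sa = tuple(int(v) for v in self.semi_axes_voxels)
        if len(sa) != 3 or any(v < 0 for v in sa):
            raise DomainError(f"semi-axes must be 3 non-negative integers, got {sa}")
        object.__setattr__(self, "semi_axes_voxels", sa)


@dataclass
class RegionPair:
    """Ipsilateral downstream region and its mirrored contralateral twin."""

    ipsilateral: BinaryMask
    contralateral: BinaryMask
    side: str  # "left" | "right"
    overlap_fraction: float
    coverage_slices: int
    warnings: list[str] = field(default_factory=list)


def threshold_hypoperfusion(
    tmax: ImageVolume, threshold_s: float = DEFAULT_TMAX_THRESHOLD_S
) -> BinaryMask:
    """Hypoperfusion mask: voxels with Tmax strictly greater than the
    threshold (seconds).  Non-finite voxels are excluded."""
    if tmax.value_kind != "tmax_seconds":
        raise DomainError(
            f"expected a tmax_seconds volume, got value_kind={tmax.value_kind!r}"
        )
    with np.errstate(invalid="ignore"):
        data = np.isfinite(tmax.data) & (tmax.data > threshold_s)
    return BinaryMask(data, tmax.spacing, tmax.origin, tmax.axis_codes)


def ellipsoid_element(params: ClosingParams) -> np.ndarray:
    """Boolean footprint of the ellipsoidal structuring element.

    The array has shape (2a+1, 2b+1, 2c+1) and is true at integer offsets
    (dx, dy, dz) with (dx/a)^2 + (dy/b)^2 + (dz/c)^2 <= 1 (inclusive); a zero
    semi-axis admits only offset 0 on that axis.  The element always contains
    the origin and is symmetric under negation.
    """
    a, b, c = params.semi_axes_voxels
    dx, dy, dz = np.meshgrid(
        np.arange(-a, a + 1), np.arange(-b, b + 1), np.arange(-c, c + 1), indexing="ij"
    )
    q = np.zeros(dx.shape, dtype=float)
    for d, s in ((dx, a), (dy, b), (dz, c)):
        if s == 0:
            q += np.where(d == 0, 0.0, np.inf)
        else:
            q += (d / s) ** 2
    return q <= 1.0


def element_offsets(params: ClosingParams) -> np.ndarray:
    """The element as an N x 3 array of integer offsets (origin-centred)."""
    a, b, c = params.semi_axes_voxels
    footprint = ellipsoid_element(params)
    return np.argwhere(footprint) - np.array([a, b, c])


def refine_downstream(hypo: BinaryMask, params: ClosingParams = ClosingParams()) -> BinaryMask:
    """Morphological closing (dilation then erosion) of the hypoperfusion mask.

    The volume is padded with background by the element's extent before
    dilation and cropped after erosion, so the image border never spuriously
    closes gaps.  The result is always a superset of the input.
    """
    a, b, c = params.semi_axes_voxels
    if (a, b, c) == (0, 0, 0):
        return hypo.like(hypo.data.copy())
    structure = ellipsoid_element(params)
    pad = ((a, a), (b, b), (c, c))
    padded = np.pad(hypo.data, pad, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=structure, border_value=0)
    closed = ndimage.binary_erosion(dilated, structure=structure, border_value=0)
    cropped = closed[a : closed.shape[0] - a or None,
                     b : closed.shape[1] - b or None,
                     c : closed.shape[2] - c or None]
    return hypo.like(cropped | hypo.data)


def build_region_pair(
    refined: BinaryMask,
    plane: MidlinePlane,
    overlap_warning_fraction: float = 0.05,
    majority_warning_fraction: float = 0.9,
) -> RegionPair:
    """Mirror the refined downstream mask to build the ipsi/contra pair.

    The ipsilateral side is the hemisphere holding the majority of the
    refined volume (canonical RAS+: positive signed distance from the plane
    is the right hemisphere).  Warnings are recorded when the mask straddles
    the midline (majority fraction < 0.9) or the mirrored region overlaps the
    original by more than ``overlap_warning_fraction``.
    """
    n_ipsi = refined.voxel_count
    if n_ipsi == 0:
        raise NoHypoperfusionError("refined downstream mask is empty")
    warnings_list: list[str] = []
    idx = np.argwhere(refined.data)
    signed = plane.signed_distance(refined.world_coordinates(idx))
    n_right = int((signed > 0).sum())
    side = "right" if n_right * 2 >= n_ipsi else "left"
    majority = max(n_right, n_ipsi - n_right) / n_ipsi
    if majority < majority_warning_fraction:
        warnings_list.append(
            f"downstream mask straddles the midline: majority fraction {majority:.3f}"
        )
    contralateral = mirror_mask(refined, plane)
    inter = int((refined.data & contralateral.data).sum())
    overlap_fraction = inter / n_ipsi
    if overlap_fraction > overlap_warning_fraction:
        warnings_list.append(
            f"ipsilateral and mirrored regions overlap by {overlap_fraction:.3f} of the "
            "ipsilateral volume"
        )
    coverage_slices = int(np.unique(idx[:, 2]).size)
    return RegionPair(
        ipsilateral=refined,
        contralateral=contralateral,
        side=side,
        overlap_fraction=float(overlap_fraction),
        coverage_slices=coverage_slices,
        warnings=warnings_list,
    )
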