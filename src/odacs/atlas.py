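"""MCA-territory masks: external atlas loading and synthetic territories.

The reference collateral score is computed over the middle cerebral artery
territory.  Real territory masks come from an external neuroanatomical atlas
(any NIfTI binary mask in any space, with a user-supplied affine to the
patient grid); for phantom studies a hemispheric slab territory is
synthesized.  Territory masks never cross the midline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError
from .geometry import AffineTransform, MidlinePlane, default_midplane, resample_to_grid
from .imaging_io import BinaryMask, GridLike, read_mask

SIDES = ("left", "right")


@dataclass(frozen=True)
class TerritorySpec:
    """Where a territory mask comes from and which hemisphere it covers."""

    source: str  # "file" | "synthetic"
    side: str  # "left" | "right"
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.source not in ("file", "synthetic"):
            raise DomainError(f"source must be 'file' or 'synthetic', got {self.source!r}")
        if self.side not in SIDES:
            raise DomainError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.source == "file" and self.path is None:
            raise DomainError("source='file' requires a path")


def synthetic_territory(
    reference: GridLike,
    plane: MidlinePlane,
    side: str,
    margin_voxels: int = 2,
) -> BinaryMask:
    """Hemispheric slab territory for phantom studies.

    Covers the chosen hemisphere minus ``margin_voxels`` at every grid border
    and a one-voxel exclusion band on either side of the midplane, so the
    mask never touches its own mirror image.
    """
    if side not in SIDES:
        raise DomainError(f"side must be one of {SIDES}, got {side!r}")
    if margin_voxels < 0:
        raise DomainError(f"margin_voxels must be >= 0, got {margin_voxels}")
    shape = reference.shape
    idx = np.indices(shape).reshape(3, -1).T
    phys = np.asarray(reference.origin) + idx * np.asarray(reference.spacing)
    signed = plane.signed_distance(phys)
    band = float(reference.spacing[0])  # one in-plane voxel on each side of the midline
    hemi = (signed <= -band) if side == "left" else (signed >= band)
    inside = np.ones(len(idx), dtype=bool)
    for axis in range(3):
        inside &= (idx[:, axis] >= margin_voxels) & (idx[:, axis] < shape[axis] - margin_voxels)
    data = np.zeros(shape, dtype=bool)
    keep = idx[hemi & inside]
    data[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return BinaryMask(data, reference.spacing, reference.origin, reference.axis_codes)


def load_territory(
    spec: TerritorySpec,
    reference: GridLike,
    transform: AffineTransform | None = None,
    plane: MidlinePlane | None = None,
    margin_voxels: int = 2,
) -> BinaryMask:
    """Territory mask on the reference grid, restricted to the spec's side.

    File-based masks are resampled nearest-neighbour onto the reference grid
    through ``transform`` (reference -> atlas physical coordinates; identity
    when omitted).  Voxels on the wrong side of the midplane (default: the
    grid-centre plane) are removed.
    """
    plane = plane or default_midplane(reference)
    if spec.source == "synthetic":
        return synthetic_territory(reference, plane, spec.side, margin_voxels)
    raw = read_mask(spec.path)
    mask = resample_to_grid(raw, reference, transform, mode="nearest")
    idx = np.argwhere(mask.data)
    if idx.size:
        signed = plane.signed_distance(mask.world_coordinates(idx))
        wrong = (signed >= 0) if spec.side == "left" else (signed <= 0)
        drop = idx[wrong]
        mask.data[drop[:, 0], drop[:, 1], drop[:, 2]] = False
    if mask.voxel_count == 0:
        raise DomainError(
            f"territory mask from {spec.path} is empty after resampling to the reference grid"
        )
    return mask
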