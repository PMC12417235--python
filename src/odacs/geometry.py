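"""Midline plane handling, mask mirroring, and grid resampling.

All reflections and resampling are computed in physical millimetre space so
that strongly anisotropic grids (e.g. 5 mm CT perfusion slices) are handled
correctly.  The left-right axis is the first array axis of a canonically
oriented volume (RAS+), so the default interhemispheric plane has normal
(1, 0, 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DomainError, GeometryError
from .imaging_io import BinaryMask, GridLike, ImageVolume


class OffGridReflectionWarning(UserWarning):
    """Some reflected voxels fell outside the grid and were dropped."""


@dataclass(frozen=True)
class MidlinePlane:
    """A physical-space plane (point + unit normal) separating hemispheres."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,) or not np.all(np.isfinite(n)):
            raise GeometryError(f"plane normal must be a finite 3-vector, got {self.normal}")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise GeometryError(f"plane normal must be unit length, |n| = {np.linalg.norm(n)}")
        p = np.asarray(self.point, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise GeometryError(f"plane point must be a finite 3-vector, got {self.point}")

    @classmethod
    def from_point_normal(cls, point: Sequence[float], normal: Sequence[float]) -> "MidlinePlane":
        """Construct with normalization of the (nonzero) normal vector."""
        n = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(n)
        if not math.isfinite(norm) or norm == 0:
            raise GeometryError("plane normal must be nonzero and finite")
        return cls(tuple(float(x) for x in point), tuple(float(x) for x in (n / norm)))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed mm distance of N x 3 physical points; positive on the side
        the normal points toward."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.point)) @ np.asarray(self.normal)

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Mirror N x 3 physical points through the plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(pts)
        return pts - 2.0 * d[:, None] * np.asarray(self.normal)

    def to_dict(self) -> dict:
        return {"point_mm": list(self.point), "normal": list(self.normal)}

    @classmethod
    def from_dict(cls, d: dict) -> "MidlinePlane":
        return cls.from_point_normal(d["point_mm"], d["normal"])


@dataclass(frozen=True)
class AffineTransform:
    """Physical-space affine map ``x -> matrix @ x + translation`` (mm)."""

    matrix: tuple  # 3x3, row-major nested tuples
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise GeometryError("affine matrix must be a finite 3x3 array")
        if abs(np.linalg.det(m)) < 1e-12 or np.linalg.cond(m) > 1e12:
            raise GeometryError("affine matrix is singular or ill-conditioned")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0))

    @classmethod
    def from_arrays(cls, matrix: np.ndarray, translation: Sequence[float]) -> "AffineTransform":
        return cls(tuple(map(tuple, np.asarray(matrix, dtype=float))),
                   tuple(float(t) for t in translation))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.matrix, dtype=float), np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        m, t = self.as_arrays()
        return np.atleast_2d(np.asarray(points, dtype=float)) @ m.T + t

    def inverse(self) -> "AffineTransform":
        m, t = self.as_arrays()
        mi = np.linalg.inv(m)
        return AffineTransform.from_arrays(mi, -mi @ t)


LEFT_RIGHT_AXIS = 0  # canonical RAS+: first axis runs left -> right


def default_midplane(volume: GridLike) -> MidlinePlane:
    """Plane through the grid's physical centre, normal along left-right.

    For a canonically oriented volume this is the fallback interhemispheric
    plane when no vendor-extracted midline is available.
    """
    shape = np.asarray(volume.shape, dtype=float)
    centre = np.asarray(volume.origin) + (shape - 1) / 2.0 * np.asarray(volume.spacing)
    normal = np.zeros(3)
    normal[LEFT_RIGHT_AXIS] = 1.0
    return MidlinePlane(tuple(centre), tuple(normal))


def _check_plane_orientation(plane: MidlinePlane) -> np.ndarray:
    """The plane normal, flipped to point along +x; errors if > 45 deg off."""
    n = np.asarray(plane.normal)
    if n[LEFT_RIGHT_AXIS] < 0:
        n = -n
    if n[LEFT_RIGHT_AXIS] < math.cos(math.radians(45.0)):
        raise GeometryError(
            "midline plane normal deviates more than 45 degrees from the left-right axis"
        )
    return n


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def mirror_mask(mask: BinaryMask, plane: MidlinePlane) -> BinaryMask:
    """Reflect every true voxel through ``plane`` in physical space.

    Each reflected physical point is assigned to the nearest voxel centre;
    exact half-voxel ties round toward the lower index for determinism.
    Reflections landing outside the grid are dropped with an
    :class:`OffGridReflectionWarning`.  Output geometry equals input geometry.
    """
    out = np.zeros(mask.shape, dtype=bool)
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        return mask.like(out)
    phys = mask.world_coordinates(idx)
    reflected = plane.reflect(phys)
    cont = (reflected - np.asarray(mask.origin)) / np.asarray(mask.spacing)
    target = np.ceil(cont - 0.5).astype(int)  # ties at .5 -> lower index
    inside = np.all((target >= 0) & (target < np.asarray(mask.shape)), axis=1)
    dropped = int((~inside).sum())
    if dropped:
        warnings.warn(
            f"{dropped}/{len(target)} reflected voxels fell outside the grid and were dropped",
            OffGridReflectionWarning,
            stacklevel=2,
        )
    kept = target[inside]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return mask.like(out)


def align_to_midplane(volume: GridLike, plane: MidlinePlane) -> tuple[GridLike, MidlinePlane]:
    """Rigidly resample so ``plane`` coincides with the grid-centre plane.

    The rigid map rotates the supplied plane normal onto the left-right axis
    and translates the plane point onto the default midplane, leaving the
    within-plane coordinates of the plane point fixed.  Scalar volumes are
    interpolated linearly, masks with nearest-neighbour.  Returns the
    resampled object and the new (default) midplane.
    """
    n = _check_plane_orientation(plane)
    target = default_midplane(volume)
    e1 = np.asarray(target.normal)
    rot = _rotation_aligning(n, e1)
    p = np.asarray(plane.point)
    q = p.copy()
    q[LEFT_RIGHT_AXIS] = np.asarray(target.point)[LEFT_RIGHT_AXIS]
    # forward map T(x) = rot @ (x - p) + q ; resampling pulls back through T^-1
    is_mask = isinstance(volume, BinaryMask)
    data = volume.data.astype(bool if is_mask else float)
    out_idx = np.indices(volume.shape, dtype=float).reshape(3, -1).T
    out_phys = np.asarray(volume.origin) + out_idx * np.asarray(volume.spacing)
    src_phys = (out_phys - q) @ rot + p  # rot.T applied: (x @ rot) == rot.T @ x rowwise
    src_idx = ((src_phys - np.asarray(volume.origin)) / np.asarray(volume.spacing)).T
    order = 0 if is_mask else 1
    resampled = ndimage.map_coordinates(
        data.astype(np.float64), src_idx.reshape(3, *volume.shape), order=order, mode="constant",
        cval=0.0, prefilter=False,
    )
    if is_mask:
        return volume.like(resampled > 0.5), target
    return (
        ImageVolume(resampled, volume.spacing, volume.origin, volume.axis_codes, volume.value_kind),
        target,
    )


def resample_to_grid(
    volume: GridLike,
    reference: GridLike,
    transform: AffineTransform | None = None,
    mode: str = "linear",
) -> GridLike:
    """Resample ``volume`` onto the grid of ``reference``.

    ``transform`` maps reference physical coordinates to the moving volume's
    physical coordinates (identity when omitted).  ``mode`` is ``"linear"``
    or ``"nearest"``; masks are always resampled nearest-neighbour.
    """
    if mode not in ("linear", "nearest"):
        raise DomainError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    transform = transform or AffineTransform.identity()
    is_mask = isinstance(volume, BinaryMask)
    order = 0 if (is_mask or mode == "nearest") else 1
    ref_idx = np.indices(reference.shape, dtype=float).reshape(3, -1).T
    ref_phys = np.asarray(reference.origin) + ref_idx * np.asarray(reference.spacing)
    mov_phys = transform.apply(ref_phys)
    mov_idx = ((mov_phys - np.asarray(volume.origin)) / np.asarray(volume.spacing)).T
    resampled = ndimage.map_coordinates(
        volume.data.astype(np.float64), mov_idx.reshape(3, *reference.shape), order=order,
        mode="constant", cval=0.0, prefilter=False,
    )
    if is_mask:
        return BinaryMask(resampled > 0.5, reference.spacing, reference.origin,
                          reference.axis_codes)
    return ImageVolume(resampled, reference.spacing, reference.origin, reference.axis_codes,
                       getattr(volume, "value_kind", "intensity"))
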