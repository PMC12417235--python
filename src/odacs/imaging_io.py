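"""NIfTI input/output, grid geometry containers, and score reports.

Volumes are represented on axis-aligned voxel grids in physical millimetre
space.  On load every image is reoriented to the closest canonical RAS+
orientation (first axis left->right), so that "mirroring across the midline"
always acts along the first array axis; the original orientation is kept for
provenance.  Voxel indices are 0-based and physical coordinates refer to voxel
centres: the centre of voxel ``i`` along an axis lies at ``origin + i *
spacing``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, DomainError, GeometryError, GridMismatchError, ImageIOError

SCHEMA_VERSION = "1"

VALUE_KINDS = ("tmax_seconds", "intensity", "probability")


def _as_triple(x: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise GeometryError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar image on an axis-aligned grid.

    Parameters
    ----------
    data:
        3D array of scalar values (floating point).
    spacing:
        Voxel size in mm per axis; all components strictly positive.
    origin:
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    axis_codes:
        Anatomical direction each axis points toward, e.g. ``("R", "A", "S")``.
    value_kind:
        ``"tmax_seconds"`` for perfusion time-to-maximum maps (values must be
        finite and non-negative), ``"intensity"`` or ``"probability"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")
    value_kind: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"volume must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive and finite, got {self.spacing}")
        if not all(math.isfinite(o) for o in self.origin):
            raise GeometryError(f"origin must be finite, got {self.origin}")
        if self.value_kind not in VALUE_KINDS:
            raise DomainError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if self.value_kind == "tmax_seconds":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and finite.min() < 0:
                raise DomainError("tmax_seconds volume contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of voxel-centre ``indices`` (N x 3)."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing the :class:`ImageVolume` grid convention."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"mask must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def physical_volume_ml(self) -> float:
        """True-voxel volume in millilitres (mm^3 / 1000)."""
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "BinaryMask":
        """A new mask with the same geometry and the given voxel data."""
        return BinaryMask(data, self.spacing, self.origin, self.axis_codes)

    def empty_like(self) -> "BinaryMask":
        return self.like(np.zeros(self.shape, dtype=bool))


GridLike = ImageVolume | BinaryMask


def assert_same_grid(a: GridLike, b: GridLike, tol_mm: float = 1e-3) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share one grid.

    Shapes must be identical; spacing and origin must agree componentwise
    within ``tol_mm``.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    for name in ("spacing", "origin"):
        va, vb = getattr(a, name), getattr(b, name)
        for axis, (x, y) in enumerate(zip(va, vb)):
            if abs(x - y) > tol_mm:
                raise GridMismatchError(
                    f"{name} mismatch on axis {axis}: {x} vs {y} (tol {tol_mm} mm)"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_OBLIQUITY_TOL = 1e-3  # max |off-diagonal| / spacing after canonical reorientation


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises assorted types
        raise ImageIOError(f"cannot read NIfTI {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {img.ndim}D")
    original_codes = nib.aff2axcodes(img.affine)
    img = nib.as_closest_canonical(img)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise GeometryError(f"{path}: non-finite or non-positive voxel spacing {spacing}")
    offdiag = lin - np.diag(np.diag(lin))
    if np.abs(offdiag).max() > _OBLIQUITY_TOL * spacing.min():
        raise GeometryError(
            f"{path}: oblique affine after canonical reorientation; resample to an "
            "axis-aligned grid first"
        )
    data = np.asarray(img.dataobj, dtype=np.float64)
    origin = aff[:3, 3]
    codes = nib.aff2axcodes(aff)
    return data, tuple(spacing), tuple(origin), codes, original_codes


def read_volume(path: str | Path, value_kind: str = "intensity") -> ImageVolume:
    """Read a 3D NIfTI file as an :class:`ImageVolume` in canonical RAS+."""
    data, spacing, origin, codes, _orig = _load_canonical(path)
    return ImageVolume(data, spacing, origin, codes, value_kind)


def read_mask(path: str | Path, threshold: float = 0.5) -> BinaryMask:
    """Read a NIfTI file and binarize it: voxels with value > ``threshold``."""
    data, spacing, origin, codes, _orig = _load_canonical(path)
    return BinaryMask(data > threshold, spacing, origin, codes)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` to NIfTI, preserving geometry."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine())
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise ImageIOError(f"cannot write {path}: {exc}") from exc


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a :class:`BinaryMask` to NIfTI as unsigned 8-bit 0/1 values."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), ImageVolume(
        mask.data.astype(np.float32), mask.spacing, mask.origin, mask.axis_codes
    ).affine())
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise ImageIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Score reports
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    """Per-patient scoring result bundle, serialized as versioned JSON.

    ``odacs`` and ``mca_cs`` are plain dictionaries produced by
    :meth:`odacs.scoring.CollateralResult.to_dict`; ``mca_cs`` is ``None``
    when no territory mask was supplied.
    """

    patient_id: str
    odacs: dict[str, Any]
    mca_cs: dict[str, Any] | None = None
    warnings: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "patient_id": self.patient_id,
            "odacs": self.odacs,
            "mca_cs": self.mca_cs,
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScoreReport":
        return cls(
            patient_id=d["patient_id"],
            odacs=d["odacs"],
            mca_cs=d.get("mca_cs"),
            warnings=list(d.get("warnings", [])),
            provenance=dict(d.get("provenance", {})),
        )


def write_report(report: ScoreReport, path: str | Path) -> None:
    """Serialize a :class:`ScoreReport` to JSON (undefined values as null)."""
    try:
        Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise ImageIOError(f"cannot write report {path}: {exc}") from exc


def read_report(path: str | Path) -> ScoreReport:
    try:
        d = json.loads(Path(path).read_text())
    except OSError as exc:
        raise ImageIOError(f"cannot read report {path}: {exc}") from exc
    return ScoreReport.from_dict(d)
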