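"""Synthetic CTA/CTP phantoms with known collateral ground truth.

Each phantom is a pair of co-registered volumes on one grid: a binary vessel
mask built from rasterized capsule (line-segment tube) vessels, and a Tmax
map with a one-sided ellipsoidal hypoperfusion lesion.  Contralateral
anatomy is the exact mirror of the ipsilateral side across the grid-centre
midplane, except for a controlled vessel deficit inside the lesion, so the
true ipsilateral/contralateral vessel-volume ratio within the (closed)
downstream region is known by direct voxel counting.  Optionally the
generator carves vessel voxels out of the lesion in the Tmax map, emulating
perfusion software that removes vessels from its analysis — the artifact
that morphological closing must repair.

Truth volumes are calibrated against brute-force voxel counts rather than
analytic capsule volumes, absorbing rasterization error: vessels are added
(and the last one trimmed voxel-by-voxel from its far end) until the
in-region count matches the target ratio.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import synthetic_territory
from .config import PipelineConfig
from .downstream import ClosingParams, refine_downstream
from .errors import GenerationError
from .geometry import MidlinePlane, default_midplane
from .imaging_io import BinaryMask, ImageVolume
from .scoring import categorize, compute_mca_cs, compute_odacs

DEFAULT_GRID_SHAPE = (96, 96, 18)
DEFAULT_SPACING_MM = (1.0, 1.0, 5.0)

#: Lesion ellipsoid semi-axes (mm) per occlusion stratum.  More distal
#: occlusions hypoperfuse smaller territories; the gradient mirrors the
#: clinical hypoperfused-volume ordering at desk scale.
STRATUM_LESION_SEMI_AXES = {
    "proximal_M1": (18.0, 18.0, 22.0),
    "distal_M1": (15.0, 15.0, 18.0),
    "M2": (11.0, 11.0, 14.0),
}
#: Cohort mix of occlusion locations (proximal M1, distal M1, M2).
STRATUM_PROBS = {"proximal_M1": 0.52, "distal_M1": 0.32, "M2": 0.16}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic patient.

    ``target_ratio`` is the desired in-region vessel-volume ratio
    (ipsilateral / contralateral); ratios up to 1.5 are supported by
    thinning the contralateral side instead.  ``noise_sd`` is the additive
    Gaussian noise level of the rendered CTA-like intensity image relative
    to unit vessel contrast (the Tmax map and masks stay noise-free).
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    n_vessels_per_side: int = 8
    vessel_radius_mm: float = 1.2
    target_ratio: float = 0.5
    lesion_center_frac: tuple[float, float, float] = (0.28, 0.5, 0.5)
    lesion_semi_axes_mm: tuple[float, float, float] = (14.0, 14.0, 18.0)
    tmax_background_s: float = 2.0
    tmax_lesion_s: float = 10.0
    carve_vessels_from_tmax: bool = False
    noise_sd: float = 0.0
    n_background_vessels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_ratio <= 1.5:
            raise GenerationError(f"target_ratio must be in [0, 1.5], got {self.target_ratio}")
        if not self.tmax_lesion_s > 6.0 > self.tmax_background_s >= 0:
            raise GenerationError(
                "require tmax_lesion_s > 6 > tmax_background_s >= 0, got "
                f"lesion={self.tmax_lesion_s}, background={self.tmax_background_s}"
            )
        if self.noise_sd < 0:
            raise GenerationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_vessels_per_side < 1:
            raise GenerationError("need at least one vessel per side")
        if not all(0 < f < 1 for f in self.lesion_center_frac):
            raise GenerationError(f"lesion_center_frac must be in (0,1), got {self.lesion_center_frac}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class PhantomTruth:
    """A generated phantom plus its ground-truth labels."""

    vessel_mask: BinaryMask
    tmax: ImageVolume
    plane: MidlinePlane
    territory_ipsi: BinaryMask
    truth_ipsi_ml: float
    truth_contra_ml: float
    truth_ratio: float
    truth_region: BinaryMask  # closed downstream region of the uncarved lesion
    spec: PhantomSpec | None = None


@dataclass
class _Capsule:
    indices: np.ndarray  # N x 3 voxel indices
    t: np.ndarray  # axis parameter in [0, 1] per voxel


def _rasterize_capsule(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius_mm: float,
) -> _Capsule:
    """Voxels whose centres lie within ``radius_mm`` of segment p0-p1."""
    lo_mm = np.minimum(p0, p1) - radius_mm
    hi_mm = np.maximum(p0, p1) + radius_mm
    lo = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        return _Capsule(np.empty((0, 3), dtype=int), np.empty(0))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    phys = origin + idx * spacing
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        t = np.zeros(len(idx))
    else:
        t = np.clip((phys - p0) @ v / vv, 0.0, 1.0)
    closest = p0 + t[:, None] * v
    inside = ((phys - closest) ** 2).sum(axis=1) <= radius_mm**2
    return _Capsule(idx[inside], t[inside])


def _sample_unit_ball(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def _paint(shape, capsules: list[_Capsule]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for cap in capsules:
        if len(cap.indices):
            out[cap.indices[:, 0], cap.indices[:, 1], cap.indices[:, 2]] = True
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build one phantom; deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = np.zeros(3)

    tmax_data = np.full(shape, spec.tmax_background_s, dtype=float)
    tmax = ImageVolume(tmax_data, tuple(spacing), tuple(origin), value_kind="tmax_seconds")
    plane = default_midplane(tmax)

    # One-sided ellipsoidal hypoperfusion lesion.
    centre = (np.asarray(shape) - 1) * np.asarray(spec.lesion_center_frac) * spacing
    idx_grid = np.indices(shape).reshape(3, -1).T
    phys = origin + idx_grid * spacing
    q = (((phys - centre) / np.asarray(spec.lesion_semi_axes_mm)) ** 2).sum(axis=1)
    lesion = np.zeros(shape, dtype=bool)
    inside = idx_grid[q <= 1.0]
    if len(inside) == 0:
        raise GenerationError("lesion ellipsoid contains no voxel centres")
    lesion[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    tmax_data[lesion] = spec.tmax_lesion_s
    side = "left" if centre[0] < plane.point[0] else "right"

    # Truth downstream region: closing of the (uncarved) thresholded lesion.
    hypo = BinaryMask(lesion, tuple(spacing), tuple(origin))
    region = refine_downstream(hypo, ClosingParams())
    flip = lambda a: a[::-1, :, :]  # noqa: E731  exact mirror of the grid-centre plane
    region_contra = flip(region.data)

    # Candidate in-lesion vessels on the ipsilateral side, clipped to the
    # downstream region so the vessel deficit stays strictly inside it.
    candidates: list[_Capsule] = []
    for _ in range(spec.n_vessels_per_side):
        for _try in range(50):
            ends = centre + 0.85 * np.asarray(spec.lesion_semi_axes_mm) * _sample_unit_ball(rng, 2)
            if np.linalg.norm(ends[1] - ends[0]) >= 0.6 * min(spec.lesion_semi_axes_mm):
                cap = _rasterize_capsule(shape, spacing, origin, ends[0], ends[1],
                                         spec.vessel_radius_mm)
                in_reg = region.data[cap.indices[:, 0], cap.indices[:, 1], cap.indices[:, 2]] \
                    if len(cap.indices) else np.zeros(0, dtype=bool)
                if in_reg.any():
                    candidates.append(_Capsule(cap.indices[in_reg], cap.t[in_reg]))
                    break
    if not candidates:
        raise GenerationError("could not place any vessel inside the lesion")

    full_union = _paint(shape, candidates)
    c_count = int((full_union & region.data).sum())
    if c_count == 0:
        raise GenerationError("candidate vessels do not intersect the downstream region")

    def trim_to(target_count: int) -> np.ndarray:
        """Union of candidates whose in-region voxel count equals target."""
        out = np.zeros(shape, dtype=bool)
        remaining = target_count
        for cap in candidates:
            if remaining <= 0:
                break
            in_reg = region.data[cap.indices[:, 0], cap.indices[:, 1], cap.indices[:, 2]]
            covered = out[cap.indices[:, 0], cap.indices[:, 1], cap.indices[:, 2]]
            new_in = in_reg & ~covered
            n_new = int(new_in.sum())
            if n_new <= remaining:
                out[cap.indices[:, 0], cap.indices[:, 1], cap.indices[:, 2]] = True
                remaining -= n_new
            else:
                # shorten the capsule: walk its voxels in axis order and keep
                # them up to the point where the needed new in-region count
                # is reached, so truth volumes are exact to the voxel
                order = np.argsort(cap.t, kind="stable")
                kept_rank = int(np.flatnonzero(new_in[order])[remaining - 1])
                sel = cap.indices[order[: kept_rank + 1]]
                out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
                remaining = 0
        return out

    if spec.target_ratio <= 1.0:
        target = int(round(spec.target_ratio * c_count))
        ipsi_in = trim_to(target)
        contra_in = flip(full_union)
    else:
        contra_target = int(round(c_count / spec.target_ratio))
        if contra_target == 0:
            raise GenerationError(
                f"target_ratio {spec.target_ratio} infeasible with {c_count} region voxels"
            )
        ipsi_in = full_union
        contra_in = flip(trim_to(contra_target))

    # Symmetric background vessels inside the territory, clear of the region.
    territory = synthetic_territory(tmax, plane, side, margin_voxels=2)
    keepout = ndimage.binary_dilation(region.data, iterations=2)
    keepout |= flip(keepout)
    bg = np.zeros(shape, dtype=bool)
    extent = np.asarray(shape) * spacing
    placed = 0
    tries = 0
    while placed < spec.n_background_vessels and tries < 400:
        tries += 1
        p0 = rng.uniform(0.08, 0.92, size=3) * extent
        p0[0] = rng.uniform(0.06, 0.42) * extent[0]  # ipsilateral-like hemisphere box
        if side == "right":
            p0[0] = extent[0] - p0[0]
        direction = _sample_unit_ball(rng)[0]
        direction /= max(np.linalg.norm(direction), 1e-9)
        p1 = p0 + direction * rng.uniform(15.0, 35.0)
        cap = _rasterize_capsule(shape, spacing, origin, p0, p1, spec.vessel_radius_mm)
        if len(cap.indices) == 0:
            continue
        ii = cap.indices
        if keepout[ii[:, 0], ii[:, 1], ii[:, 2]].any():
            continue
        if not territory.data[ii[:, 0], ii[:, 1], ii[:, 2]].all():
            continue
        mirrored = flip(_paint(shape, [cap]))
        if (mirrored & keepout).any() or (mirrored & ~territory_mirror(territory)).any():
            continue
        bg |= _paint(shape, [cap]) | mirrored
        placed += 1

    vessel_data = ipsi_in | contra_in | bg
    vessels = BinaryMask(vessel_data, tuple(spacing), tuple(origin))

    vox_ml = float(np.prod(spacing)) / 1000.0
    truth_ipsi = int((ipsi_in & region.data).sum()) * vox_ml
    truth_contra = int((contra_in & region_contra).sum()) * vox_ml
    truth_ratio = truth_ipsi / truth_contra if truth_contra > 0 else float("nan")

    if spec.carve_vessels_from_tmax:
        carve = vessel_data & lesion
        tmax_data[carve] = spec.tmax_background_s

    return PhantomTruth(
        vessel_mask=vessels,
        tmax=ImageVolume(tmax_data, tuple(spacing), tuple(origin), value_kind="tmax_seconds"),
        plane=plane,
        territory_ipsi=territory,
        truth_ipsi_ml=truth_ipsi,
        truth_contra_ml=truth_contra,
        truth_ratio=truth_ratio,
        truth_region=region,
        spec=spec,
    )


def territory_mirror(territory: BinaryMask) -> np.ndarray:
    """Mirror of a territory mask across the grid-centre plane (array)."""
    return territory.data[::-1, :, :]


def render_cta(
    vessel_mask: BinaryMask, contrast: float = 1.0, noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageVolume:
    """CTA-like intensity image: vessel contrast plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    data = vessel_mask.data.astype(float) * contrast
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return ImageVolume(data, vessel_mask.spacing, vessel_mask.origin, vessel_mask.axis_codes,
                       value_kind="intensity")


def fallback_segment(
    cta_like: ImageVolume, intensity_threshold: float, min_component_voxels: int = 0
) -> BinaryMask:
    """Threshold segmenter standing in for a trained vessel-segmentation model.

    Voxels strictly above the intensity threshold are vessel; connected
    components (26-connectivity) smaller than ``min_component_voxels`` are
    removed as noise.
    """
    data = cta_like.data > intensity_threshold
    if min_component_voxels > 0 and data.any():
        labels, n = ndimage.label(data, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_component_voxels)
        data &= ~np.isin(labels, small[small > 0])
    return BinaryMask(data, cta_like.spacing, cta_like.origin, cta_like.axis_codes)


def generate_cohort(
    n: int,
    seed: int,
    ratio_range: tuple[float, float] = (0.1, 1.1),
    carve_vessels_from_tmax: bool = True,
    config: PipelineConfig | None = None,
    keep_phantoms: bool = False,
) -> tuple[list[PhantomTruth], pd.DataFrame]:
    """Simulate a scored cohort of ``n`` synthetic patients.

    Occlusion locations are drawn with the clinical mix (52% proximal M1,
    32% distal M1, 16% M2); lesion size decreases with more distal strata;
    target ratios are uniform on ``ratio_range``.  Each phantom is scored by
    the full pipeline (ODACS and MCA-CS), and two simulated raters provide
    noisy categorical readings of the truth ratio (rating noise SD 0.08 and
    0.12).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise GenerationError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    locations = list(STRATUM_PROBS)
    probs = np.asarray(list(STRATUM_PROBS.values()))
    rows: list[dict[str, Any]] = []
    phantoms: list[PhantomTruth] = []
    for i in range(n):
        loc = str(rng.choice(locations, p=probs))
        spec = PhantomSpec(
            target_ratio=float(rng.uniform(*ratio_range)),
            lesion_semi_axes_mm=STRATUM_LESION_SEMI_AXES[loc],
            carve_vessels_from_tmax=carve_vessels_from_tmax,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = generate_phantom(spec)
        odacs_res, _pair = compute_odacs(truth.vessel_mask, truth.tmax, truth.plane, config)
        mca_res = compute_mca_cs(truth.vessel_mask, truth.territory_ipsi, truth.plane,
                                 config.low_relax, config.high_relax)
        row: dict[str, Any] = {
            "patient_id": f"P{i:03d}",
            "occlusion_location": loc,
            "odacs_ratio": odacs_res.ratio,
            "mca_ratio": mca_res.ratio,
            "odacs_category": odacs_res.category,
            "mca_category": mca_res.category,
            "truth_ratio": truth.truth_ratio,
            "hypoperfused_ml": truth.truth_region.physical_volume_ml,
        }
        for rater, sd in (("rater_R1", 0.08), ("rater_R2", 0.12)):
            noisy = max(float(truth.truth_ratio + rng.normal(0.0, sd)), 0.0)
            row[rater] = categorize(noisy, config.low_relax, config.high_relax)
        rows.append(row)
        if keep_phantoms:
            phantoms.append(truth)
    return phantoms, pd.DataFrame(rows)
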