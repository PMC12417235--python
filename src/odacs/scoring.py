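"""Collateral scoring: vessel volumes, quantitative ratio, Tan categories.

The quantitative collateral score is the ratio of segmented vessel volume in
the ipsilateral region of interest to that in its mirrored contralateral
counterpart.  For ODACS the region is the refined occlusion-downstream area;
for the reference MCA-CS it is the middle-cerebral-artery territory.  The
ratio is categorized on the 4-level ordinal Tan scale with relaxed outer
boundaries (filling < 5% of the contralateral side counts as absent, > 95%
as complete), and optionally on the extended 6-level scale that splits
categories 1 and 2 into a/b halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from .atlas import load_territory  # noqa: F401  (re-export convenience)
from .config import PipelineConfig
from .downstream import (
    ClosingParams,
    RegionPair,
    build_region_pair,
    refine_downstream,
    threshold_hypoperfusion,
)
from .errors import DomainError
from .geometry import MidlinePlane, mirror_mask
from .imaging_io import BinaryMask, ImageVolume, assert_same_grid

TAN_CATEGORIES = (0, 1, 2, 3)
EXTENDED_CATEGORIES = ("0", "1a", "1b", "2a", "2b", "3")


@dataclass
class CollateralResult:
    """Outcome of scoring one region pair for one method."""

    method: str  # "ODACS" | "MCA_CS"
    ipsi_vessel_ml: float
    contra_vessel_ml: float
    ratio: float | None
    category: int | None
    extended_category: str | None
    dichotomy: str | None  # "poor" | "good"
    undefined_reason: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "ipsi_vessel_ml": self.ipsi_vessel_ml,
            "contra_vessel_ml": self.contra_vessel_ml,
            "ratio": self.ratio,
            "category": self.category,
            "extended_category": self.extended_category,
            "dichotomy": self.dichotomy,
            "undefined_reason": self.undefined_reason,
        }


def vessel_volume_in_region(vessels: BinaryMask, region: BinaryMask) -> float:
    """Physical volume (mL) of the vessel segmentation inside a region."""
    assert_same_grid(vessels, region)
    count = int((vessels.data & region.data).sum())
    sx, sy, sz = vessels.spacing
    return count * sx * sy * sz / 1000.0


def quantitative_score(ipsi_ml: float, contra_ml: float) -> float | None:
    """Ipsilateral / contralateral vessel-volume ratio; ``None`` (undefined)
    when the contralateral volume is zero.  Values above 1 are permitted."""
    if ipsi_ml < 0 or contra_ml < 0:
        raise DomainError(f"vessel volumes must be non-negative, got ({ipsi_ml}, {contra_ml})")
    if contra_ml == 0:
        return None
    return ipsi_ml / contra_ml


def categorize(ratio: float, low_relax: float = 0.05, high_relax: float = 0.95) -> int:
    """Tan category of a quantitative ratio with relaxed outer boundaries.

    CS 0 iff ratio < low_relax; CS 1 iff low_relax <= ratio <= 0.5;
    CS 2 iff 0.5 < ratio <= high_relax; CS 3 iff ratio > high_relax.
    Boundary points join the inner categories, preserving the original Tan
    "<= 50%" inclusivity; ratios above 1 map to CS 3.
    """
    _check_relax(low_relax, high_relax)
    if not math.isfinite(ratio) or ratio < 0:
        raise DomainError(f"ratio must be finite and >= 0, got {ratio}")
    if ratio < low_relax:
        return 0
    if ratio <= 0.5:
        return 1
    if ratio <= high_relax:
        return 2
    return 3


def categorize_extended(ratio: float, low_relax: float = 0.05, high_relax: float = 0.95) -> str:
    """Extended Tan category: splits CS 1 at 25% and CS 2 at 75% filling.

    1a spans [low_relax, 0.25], 1b (0.25, 0.5]; 2a (0.5, 0.75],
    2b (0.75, high_relax] — the a/b split refines only the interior of the
    relaxed base categories.
    """
    base = categorize(ratio, low_relax, high_relax)
    if base == 1:
        return "1a" if ratio <= 0.25 else "1b"
    if base == 2:
        return "2a" if ratio <= 0.75 else "2b"
    return str(base)


def dichotomize(category: int | None) -> str | None:
    """Clinically relevant dichotomy: good (CS 2-3) vs poor (CS 0-1)."""
    if category is None:
        return None
    if category not in TAN_CATEGORIES:
        raise DomainError(f"category must be in {TAN_CATEGORIES}, got {category}")
    return "good" if category >= 2 else "poor"


def _check_relax(low_relax: float, high_relax: float) -> None:
    if not (0 < low_relax < 0.5 < high_relax < 1):
        raise DomainError(
            f"require 0 < low_relax < 0.5 < high_relax < 1, got ({low_relax}, {high_relax})"
        )


def score_region_pair(
    vessels: BinaryMask,
    ipsi_region: BinaryMask,
    contra_region: BinaryMask,
    method: str,
    low_relax: float = 0.05,
    high_relax: float = 0.95,
) -> CollateralResult:
    """Score a prepared ipsi/contra region pair against a vessel mask."""
    ipsi_ml = vessel_volume_in_region(vessels, ipsi_region)
    contra_ml = vessel_volume_in_region(vessels, contra_region)
    ratio = quantitative_score(ipsi_ml, contra_ml)
    if ratio is None:
        return CollateralResult(
            method=method,
            ipsi_vessel_ml=ipsi_ml,
            contra_vessel_ml=contra_ml,
            ratio=None,
            category=None,
            extended_category=None,
            dichotomy=None,
            undefined_reason="zero contralateral vessel volume",
        )
    cat = categorize(ratio, low_relax, high_relax)
    return CollateralResult(
        method=method,
        ipsi_vessel_ml=ipsi_ml,
        contra_vessel_ml=contra_ml,
        ratio=ratio,
        category=cat,
        extended_category=categorize_extended(ratio, low_relax, high_relax),
        dichotomy=dichotomize(cat),
    )


def compute_odacs(
    vessels: BinaryMask,
    tmax: ImageVolume,
    plane: MidlinePlane,
    config: PipelineConfig | None = None,
) -> tuple[CollateralResult, RegionPair]:
    """Full occlusion-downstream area collateral score for one patient.

    Thresholds the Tmax map, refines the hypoperfused area by morphological
    closing, mirrors it across the midline plane, and scores the vessel
    volumes of the resulting region pair.  Deterministic for fixed inputs
    and configuration.  Raises :class:`~odacs.errors.NoHypoperfusionError`
    when the thresholded map is empty (such patients are excluded).
    """
    config = config or PipelineConfig()
    assert_same_grid(vessels, tmax)
    hypo = threshold_hypoperfusion(tmax, config.tmax_threshold_s)
    refined = refine_downstream(hypo, ClosingParams(config.closing_semi_axes))
    pair = build_region_pair(
        refined, plane, overlap_warning_fraction=config.overlap_warning_fraction
    )
    result = score_region_pair(
        vessels, pair.ipsilateral, pair.contralateral, "ODACS",
        config.low_relax, config.high_relax,
    )
    return result, pair


def compute_mca_cs(
    vessels: BinaryMask,
    territory_ipsi: BinaryMask,
    plane: MidlinePlane,
    low_relax: float = 0.05,
    high_relax: float = 0.95,
) -> CollateralResult:
    """Reference MCA-territory collateral score.

    The contralateral territory is the mirror of the supplied ipsilateral
    territory mask across the midline plane; the scoring contract is the
    same as for ODACS with the territory replacing the downstream region.
    """
    assert_same_grid(vessels, territory_ipsi)
    if territory_ipsi.voxel_count == 0:
        raise DomainError("territory mask is empty")
    contra = mirror_mask(territory_ipsi, plane)
    return score_region_pair(
        vessels, territory_ipsi, contra, "MCA_CS", low_relax, high_relax
    )


def region_vessel_overlays(
    vessels: BinaryMask, pair: RegionPair
) -> tuple[BinaryMask, BinaryMask]:
    """Vessels restricted to the ipsilateral and contralateral regions.

    These are the two labelled masks (the red/green rendering of the
    workflow figure) for external visualization.
    """
    ipsi = vessels.like(vessels.data & pair.ipsilateral.data)
    contra = vessels.like(vessels.data & pair.contralateral.data)
    return ipsi, contra
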