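"""Pipeline configuration with YAML loading and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Tunable parameters of the collateral-scoring pipeline.

    Attributes
    ----------
    tmax_threshold_s:
        Hypoperfusion threshold in seconds; voxels strictly above it form
        the downstream area.  Default 6.0 s, the conventional definition of
        hypoperfused tissue across CTP software.
    closing_semi_axes:
        Ellipsoid semi-axes (voxels, x/y/z) of the closing element that
        re-includes carved-out vessels.  Default [10, 10, 1]; [0, 0, 0]
        disables the refinement.
    low_relax / high_relax:
        Relaxed category boundaries of the Tan scale: filling below
        ``low_relax`` counts as absent collaterals (CS 0) and above
        ``high_relax`` as complete filling (CS 3), absorbing minor false
        positive segmentations.  Defaults 0.05 and 0.95.
    overlap_warning_fraction:
        Warn when the mirrored region overlaps the ipsilateral one by more
        than this fraction (midline-straddling lesions).
    """

    tmax_threshold_s: float = 6.0
    closing_semi_axes: tuple[int, int, int] = (10, 10, 1)
    low_relax: float = 0.05
    high_relax: float = 0.95
    overlap_warning_fraction: float = 0.05
    save_intermediates: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.closing_semi_axes = tuple(int(v) for v in self.closing_semi_axes)
        if len(self.closing_semi_axes) != 3 or any(v < 0 for v in self.closing_semi_axes):
            raise ConfigError(
                f"closing_semi_axes must be 3 non-negative integers, got {self.closing_semi_axes}"
            )
        if not self.tmax_threshold_s > 0:
            raise ConfigError(f"tmax_threshold_s must be > 0, got {self.tmax_threshold_s}")
        if not (0 < self.low_relax < 0.5 < self.high_relax < 1):
            raise ConfigError(
                "relaxations must satisfy 0 < low_relax < 0.5 < high_relax < 1, got "
                f"low_relax={self.low_relax}, high_relax={self.high_relax}"
            )
        if not 0 <= self.overlap_warning_fraction <= 1:
            raise ConfigError(
                f"overlap_warning_fraction must be in [0, 1], got {self.overlap_warning_fraction}"
            )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["closing_semi_axes"] = list(self.closing_semi_axes)
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; defaults for absent keys."""
    if path is None:
        return PipelineConfig()
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
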