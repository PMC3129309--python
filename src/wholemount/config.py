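"""Analysis configuration: defaults, validation, serialisation, hashing.

Every analysis-affecting knob of the pipeline lives in one
:class:`AnalysisConfig` so that a batch run is fully described by its config
hash.  Unknown keys are rejected rather than ignored — a typo in a config
file must fail loudly, not silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

from .calibration import ODCalibration, SpatialCalibration

__all__ = ["AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration with documented defaults.

    Parameters
    ----------
    cm_per_pixel
        Spatial calibration, cm per pixel edge. Default 0.005 cm (50 µm),
        typical of a low-magnification whole-mount composite.
    od_model, od_max
        Optical-density curve: ``"log"`` (default) or ``"linear"``; OD at
        gray 0 (default 2.4).
    flatten_kernel_radius
        Disc radius (px) for background flattening; ``None`` (default) uses
        one eighth of the smaller image dimension, which comfortably exceeds
        duct width while tracking illumination-scale shading.
    saturate_fraction
        Quantile saturated at each end of the contrast stretch.  Default 0.0
        (pure min–max): a fixed saturated fraction inverts the stretch when
        the stained tree occupies less of the frame than that fraction, as
        it does for rudimentary glands, so the pipeline anchors the stretch
        at the observed extremes and leaves saturation to the threshold's
        guard band.
    dense_threshold
        Upper gray level of the dense (epithelium) selection on the enhanced
        image, in [0, 254].  Default 200: the enhanced fat pad sits within a
        few gray levels of white but retains residual texture and sensor
        noise, so a guard band below 254 keeps it out of the dense mask.
    wand_tolerance
        Gray-level tolerance of the lymph-node flood-fill wand (default 32).
    density_convention
        ``"mean_of_ratios"`` (default): per-specimen density percentages are
        averaged across a group.  ``"ratio_of_means"``: group mean part over
        group mean total.
    seed
        RNG seed stamped into outputs for provenance.
    """

    cm_per_pixel: float = 0.005
    od_model: str = "log"
    od_max: float = 2.4
    flatten_kernel_radius: int | None = None
    saturate_fraction: float = 0.0
    dense_threshold: int = 200
    wand_tolerance: int = 32
    density_convention: str = "mean_of_ratios"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cm_per_pixel > 0):
            raise ConfigError(f"cm_per_pixel must be positive, got {self.cm_per_pixel}")
        if self.od_model not in ("log", "linear"):
            raise ConfigError(f"unknown od_model {self.od_model!r}")
        if not (0 <= self.saturate_fraction < 0.5):
            raise ConfigError(f"saturate_fraction out of range: {self.saturate_fraction}")
        if not (0 <= self.dense_threshold <= 254):
            raise ConfigError(f"dense_threshold out of [0, 254]: {self.dense_threshold}")
        if self.wand_tolerance < 0:
            raise ConfigError("wand_tolerance must be non-negative")
        if self.density_convention not in ("mean_of_ratios", "ratio_of_means"):
            raise ConfigError(f"unknown density_convention {self.density_convention!r}")
        if self.flatten_kernel_radius is not None and self.flatten_kernel_radius < 1:
            raise ConfigError("flatten_kernel_radius must be >= 1 (or None for auto)")

    # -- derived calibrations -------------------------------------------------

    def spatial_calibration(self) -> SpatialCalibration:
        return SpatialCalibration(cm_per_pixel=self.cm_per_pixel)

    def od_calibration(self) -> ODCalibration:
        return ODCalibration(model=self.od_model, od_max=self.od_max)

    def kernel_radius_for(self, shape: tuple[int, int]) -> int:
        if self.flatten_kernel_radius is not None:
            return int(self.flatten_kernel_radius)
        return max(1, min(shape) // 8)

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash over the analysis-affecting fields."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
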