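"""Run configuration: every tunable of every stage in one flat mapping.

Configs are stored as flat key–value YAML.  Unknown keys are rejected (they
are almost always typos), omitted keys take the documented defaults, and
physical parameters are validated on load.  The paper-stated constants —
the SAβGal hue window [0.265, 0.58], the 6 µm phalloidin closing element,
the 50 µm / 0.8 sphere filter and α = 0.05 — are the defaults here, never
hard-coded in the stage functions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


@dataclass
class RunConfig:
    # --- shared -----------------------------------------------------------
    pixel_size: float = 1.0  # µm / pixel, used when images carry no metadata
    seed: int = 0
    output_dir: str = "."

    # --- immunofluorescence quantification --------------------------------
    channel_dapi: int = 0
    channel_phalloidin: int = 1
    channel_marker: int = 2
    normalization: str = "minmax"  # or "percentile"
    closing_radius: float = 6.0  # µm, phalloidin closing disc
    nucleus_min_area: float = 10.0  # µm², speck floor

    # --- SAβGal scoring ----------------------------------------------------
    hue_min: float = 0.265
    hue_max: float = 0.58
    saturation_min: float = 0.1  # 0 disables the achromatic-pixel gate
    cell_min_area: float = 50.0  # µm²
    sobel_dilation_px: int = 2
    sobel_erosion_px: int = 3

    # --- neurosphere detection ---------------------------------------------
    min_diameter: float = 50.0  # µm, strict lower bound
    max_eccentricity: float = 0.8  # strict upper bound
    large_sphere_area: float = 1e5  # µm²
    max_sphere_diameter: float = 300.0  # µm, sets background/homomorphic scales
    entropy_radius: int = 12  # px
    watershed_sigma: float = 4.0  # px
    watershed_h: float = 2.0  # px, h-maxima suppression
    clahe_clip: float = 0.02
    clahe_tiles: int = 8
    well_fallback: str = "none"  # or "hough"

    # --- synergy -----------------------------------------------------------
    alpha: float = 0.05
    pairing: str = "matched"  # or "pairwise"
    multiplicity: str = "joint"  # or "per_dose"

    def validate(self) -> None:
        def require(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        require(self.pixel_size > 0, f"pixel_size must be > 0, got {self.pixel_size}")
        require(0.0 <= self.hue_min <= self.hue_max <= 1.0,
                "hue window must satisfy 0 <= hue_min <= hue_max <= 1")
        require(0.0 <= self.saturation_min <= 1.0,
                "saturation_min must lie in [0, 1]")
        require(self.closing_radius > 0, "closing_radius must be > 0")
        require(self.min_diameter > 0, "min_diameter must be > 0")
        require(0.0 < self.max_eccentricity <= 1.0,
                "max_eccentricity must lie in (0, 1]")
        require(0.0 < self.alpha < 1.0, "alpha must lie in (0, 1)")
        require(self.normalization in ("minmax", "percentile"),
                f"unknown normalization {self.normalization!r}")
        require(self.pairing in ("matched", "pairwise"),
                f"unknown pairing {self.pairing!r}")
        require(self.multiplicity in ("joint", "per_dose"),
                f"unknown multiplicity {self.multiplicity!r}")
        require(self.well_fallback in ("none", "hough"),
                f"unknown well_fallback {self.well_fallback!r}")
        require(self.entropy_radius >= 1, "entropy_radius must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a validated config from a flat YAML file and/or overrides.

    An empty or missing mapping yields all defaults; unknown keys raise
    :class:`ConfigError` naming the key.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as flat key–value YAML (round-trips with load)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
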