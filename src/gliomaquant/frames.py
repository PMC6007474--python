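"""Core in-memory containers for calibrated microscopy frames.

Every quantification stage consumes one of two containers: a single-channel
:class:`IntensityFrame` (fluorescence or brightfield) or an RGB
:class:`ColorFrame` (histochemistry).  Both carry the physical pixel size in
micrometres so that downstream geometry (areas, diameters, structuring-element
radii) is always expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityFrame", "ColorFrame"]


@dataclass
class IntensityFrame:
    """A single-channel image with physical calibration.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Non-negative pixel intensities in arbitrary units.
    pixel_size : float
        Edge length of one pixel in micrometres (µm/pixel), > 0.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("IntensityFrame requires a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return float(self.pixel_size) ** 2


@dataclass
class ColorFrame:
    """An RGB image with physical calibration.

    ``pixels`` has shape (rows, cols, 3).  Float data are expected in [0, 1];
    integer data are interpreted on their native range and converted to float
    in [0, 1] on construction.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[-1] != 3 or arr.size == 0:
            raise ValueError("ColorFrame requires a (rows, cols, 3) array")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        self.pixels = arr
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return float(self.pixel_size) ** 2
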