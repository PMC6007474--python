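"""SAβGal positive-area scoring of RGB brightfield images.

Cells are segmented from the luminance channel by Sobel gradient
thresholding (dilate → fill holes → erode to produce solid regions), and
pixels inside cells are called SAβGal-positive when their HSV hue falls in
the closed window [0.265, 0.58] — the blue-green band of the X-gal reaction
product — with a small minimum-saturation gate that keeps near-achromatic
pixels, whose hue is numerically arbitrary, from counting as positive.
The per-frame readout is positive area / cell area; condition-level
aggregation pools areas across frames before dividing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import dilation, disk, erosion, remove_small_objects

from .frames import ColorFrame

__all__ = [
    "HUE_MIN",
    "HUE_MAX",
    "SabgalResult",
    "segment_cells_brightfield",
    "sabgal_positive_mask",
    "sabgal_fraction",
    "summarize_condition",
]

#: Closed HSV hue window of the SAβGal reaction product.
HUE_MIN = 0.265
HUE_MAX = 0.58

# Guard against float round-off in RGB↔HSV round trips at the window edges;
# far below the hue resolution of 8-bit colour data.
_HUE_EPS = 1e-9


@dataclass
class SabgalResult:
    """Per-frame SAβGal-positive area fraction.

    ``positive_fraction`` is ``nan`` (undefined) when no cell area was found.
    """

    frame_id: str
    cell_area: float  # µm²
    positive_area: float  # µm²
    positive_fraction: float

    @property
    def defined(self) -> bool:
        return self.cell_area > 0


def segment_cells_brightfield(frame: ColorFrame, min_area: float = 50.0,
                              dilation_radius: int = 2,
                              erosion_radius: int = 3) -> np.ndarray:
    """Segment cell regions from an RGB brightfield image via Sobel edges.

    The Sobel gradient magnitude of the luminance image is Otsu-thresholded;
    the edge map is dilated, hole-filled and eroded back to produce solid
    regions, and objects below ``min_area`` µm² are dropped.  The default
    erosion exceeds the dilation by the half-width of the Sobel edge band
    (~1 px), so the recovered outline sits on the true cell boundary rather
    than outside it.
    """
    gray = rgb2gray(frame.pixels)
    if gray.max() - gray.min() < 1e-12:
        warnings.warn("uniform brightfield image: returning an empty cell mask",
                      stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    grad = sobel(gray)
    edges = grad > threshold_otsu(grad)
    solid = dilation(edges, disk(dilation_radius))
    solid = ndi.binary_fill_holes(solid)
    solid = erosion(solid, disk(erosion_radius))
    min_px = max(int(np.ceil(min_area / frame.pixel_area)), 1)
    return remove_small_objects(solid, max_size=min_px - 1)


def sabgal_positive_mask(frame: ColorFrame, cell_mask: np.ndarray,
                         hue_min: float = HUE_MIN, hue_max: float = HUE_MAX,
                         saturation_min: float = 0.1) -> np.ndarray:
    """Pixels inside cells whose hue falls in the closed stain window.

    Set ``saturation_min=0`` for a literal hue-only threshold.
    """
    if cell_mask.shape != frame.shape:
        raise ValueError("cell_mask shape must match the frame")
    hsv = rgb2hsv(frame.pixels)
    hue, sat = hsv[..., 0], hsv[..., 1]
    in_window = (hue >= hue_min - _HUE_EPS) & (hue <= hue_max + _HUE_EPS)
    return in_window & (sat >= saturation_min) & cell_mask


def sabgal_fraction(frame: ColorFrame, frame_id: str = "",
                    hue_min: float = HUE_MIN, hue_max: float = HUE_MAX,
                    saturation_min: float = 0.1, min_area: float = 50.0,
                    dilation_radius: int = 2, erosion_radius: int = 3,
                    cell_mask: np.ndarray | None = None) -> SabgalResult:
    """Fraction of cell area positive for SAβGal in one frame.

    Composes :func:`segment_cells_brightfield` and
    :func:`sabgal_positive_mask`; a precomputed ``cell_mask`` may be supplied
    to bypass segmentation.
    """
    if cell_mask is None:
        cell_mask = segment_cells_brightfield(frame, min_area=min_area,
                                              dilation_radius=dilation_radius,
                                              erosion_radius=erosion_radius)
    positive = sabgal_positive_mask(frame, cell_mask, hue_min, hue_max,
                                    saturation_min)
    px = frame.pixel_area
    cell_area = float(cell_mask.sum()) * px
    positive_area = float(positive.sum()) * px
    fraction = positive_area / cell_area if cell_area > 0 else float("nan")
    return SabgalResult(frame_id=frame_id, cell_area=cell_area,
                        positive_area=positive_area,
                        positive_fraction=fraction)


def summarize_condition(results: list[SabgalResult],
                        condition: str = "") -> SabgalResult:
    """Pooled-area SAβGal fraction for a condition.

    Total positive area across frames is divided by total cell area (not the
    mean of per-frame fractions), matching the per-condition readout.
    """
    cell = sum(r.cell_area for r in results)
    pos = sum(r.positive_area for r in results)
    fraction = pos / cell if cell > 0 else float("nan")
    return SabgalResult(frame_id=condition, cell_area=cell,
                        positive_area=pos, positive_fraction=fraction)
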