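"""Nuclear-vs-cytoplasmic quantification of immunofluorescence frames.

The nuclear compartment is segmented from the DAPI channel (min–max
normalisation, global Otsu threshold, speck removal) and the cell footprint
from the phalloidin channel (normalisation, grey-scale morphological closing
with a 6 µm disc, Otsu threshold).  The cytoplasmic compartment is the cell
footprint minus the nuclear mask, so the two compartments are disjoint by
construction.  Mean marker intensity is then measured over each compartment
per frame, and frames are averaged with equal weight within a condition set
after removing observer-excluded frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from .frames import IntensityFrame

__all__ = [
    "CompartmentMasks",
    "CompartmentIntensity",
    "SetSummary",
    "CalibrationError",
    "normalize_channel",
    "segment_nuclei",
    "segment_cytoplasm",
    "quantify_frame",
    "summarize_set",
]


class CalibrationError(ValueError):
    """Raised when the physical calibration makes a step meaningless."""


@dataclass
class CompartmentMasks:
    """Paired boolean masks for the nuclear and cytoplasmic compartments."""

    nuclear: np.ndarray
    cytoplasmic: np.ndarray

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.cytoplasmic.shape:
            raise ValueError("compartment masks must share one shape")
        if np.any(self.nuclear & self.cytoplasmic):
            raise ValueError("nuclear and cytoplasmic masks must be disjoint")


@dataclass
class CompartmentIntensity:
    """Per-frame mean marker intensity and area for each compartment.

    A compartment with zero area has ``nan`` mean and is flagged through
    ``nuclear_defined`` / ``cytoplasmic_defined``.
    """

    frame_id: str
    nuclear_mean: float
    cytoplasmic_mean: float
    nuclear_area: float  # µm²
    cytoplasmic_area: float  # µm²

    @property
    def nuclear_defined(self) -> bool:
        return self.nuclear_area > 0

    @property
    def cytoplasmic_defined(self) -> bool:
        return self.cytoplasmic_area > 0


@dataclass
class SetSummary:
    """Equal-weight average of per-frame compartment means in one condition."""

    condition: str
    n_frames: int
    nuclear_mean: float
    nuclear_sd: float
    cytoplasmic_mean: float
    cytoplasmic_sd: float
    excluded: list[str] = field(default_factory=list)


def normalize_channel(pixels: np.ndarray, mode: str = "minmax",
                      percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Rescale a channel to [0, 1].

    ``minmax`` divides out the full intensity range; ``percentile`` clips to
    the given percentiles first, which is more robust to hot pixels.  A flat
    channel is returned as all zeros.
    """
    x = np.asarray(pixels, dtype=np.float64)
    if mode == "minmax":
        lo, hi = x.min(), x.max()
    elif mode == "percentile":
        lo, hi = np.percentile(x, percentiles)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def segment_nuclei(dapi: IntensityFrame, min_area: float = 10.0,
                   normalization: str = "minmax") -> np.ndarray:
    """Threshold the normalised DAPI channel into a nuclear mask.

    Parameters
    ----------
    min_area : float
        Objects below this area (µm²) are removed as specks.
    """
    norm = normalize_channel(dapi.pixels, normalization)
    if not norm.any():
        warnings.warn("flat DAPI frame: returning an empty nuclear mask",
                      stacklevel=2)
        return np.zeros(dapi.shape, dtype=bool)
    mask = norm > threshold_otsu(norm)
    min_px = max(int(np.ceil(min_area / dapi.pixel_area)), 1)
    return remove_small_objects(mask, max_size=min_px - 1)


def segment_cytoplasm(phalloidin: IntensityFrame, nuclear_mask: np.ndarray,
                      closing_radius: float = 6.0,
                      normalization: str = "minmax") -> np.ndarray:
    """Segment the cytoplasmic compartment from the phalloidin channel.

    The normalised channel is grey-scale closed with a disc of radius
    ``closing_radius`` µm (bridging sub-resolution gaps in the actin stain),
    Otsu-thresholded into a cell footprint, and the nuclear mask subtracted.
    """
    if nuclear_mask.shape != phalloidin.shape:
        raise ValueError("nuclear_mask shape must match the phalloidin frame")
    if closing_radius / phalloidin.pixel_size < 1.0:
        raise CalibrationError(
            f"closing radius {closing_radius} µm is below one pixel at "
            f"{phalloidin.pixel_size} µm/pixel")
    radius_px = int(round(closing_radius / phalloidin.pixel_size))
    norm = normalize_channel(phalloidin.pixels, normalization)
    if not norm.any():
        warnings.warn("flat phalloidin frame: returning an empty mask",
                      stacklevel=2)
        return np.zeros(phalloidin.shape, dtype=bool)
    closed = closing(norm, disk(radius_px))
    footprint = closed > threshold_otsu(closed)
    return footprint & ~nuclear_mask


def quantify_frame(marker: IntensityFrame, masks: CompartmentMasks,
                   frame_id: str = "") -> CompartmentIntensity:
    """Mean marker intensity over each compartment of one frame."""
    if masks.nuclear.shape != marker.shape:
        raise ValueError("mask shape must match the marker frame")
    px_area = marker.pixel_area
    n_nuc = int(masks.nuclear.sum())
    n_cyt = int(masks.cytoplasmic.sum())
    return CompartmentIntensity(
        frame_id=frame_id,
        nuclear_mean=float(marker.pixels[masks.nuclear].mean()) if n_nuc else float("nan"),
        cytoplasmic_mean=float(marker.pixels[masks.cytoplasmic].mean()) if n_cyt else float("nan"),
        nuclear_area=n_nuc * px_area,
        cytoplasmic_area=n_cyt * px_area,
    )


def summarize_set(results: list[CompartmentIntensity], condition: str = "",
                  excluded_frames: list[str] | tuple[str, ...] = ()) -> SetSummary:
    """Average per-frame compartment means within a condition set.

    Frames named in ``excluded_frames`` (observer QC) are dropped before
    averaging; frames with an undefined compartment do not contribute to
    that compartment's average.  Frames are weighted equally, not by area.
    """
    excluded = set(excluded_frames)
    kept = [r for r in results if r.frame_id not in excluded]
    if not kept:
        raise ValueError("all frames excluded: nothing to summarize")

    def stats(values: list[float]) -> tuple[float, float]:
        vals = [v for v in values if np.isfinite(v)]
        if not vals:
            return float("nan"), float("nan")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return mean, sd

    nuc_mean, nuc_sd = stats([r.nuclear_mean for r in kept])
    cyt_mean, cyt_sd = stats([r.cytoplasmic_mean for r in kept])
    dropped = sorted(excluded & {r.frame_id for r in results})
    return SetSummary(
        condition=condition,
        n_frames=len(kept),
        nuclear_mean=nuc_mean,
        nuclear_sd=nuc_sd,
        cytoplasmic_mean=cyt_mean,
        cytoplasmic_sd=cyt_sd,
        excluded=dropped,
    )
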