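"""Neurosphere detection and sizing in stitched whole-well brightfield images.

The processing chain mirrors standard practice for whole-well sphere assays:

1. :func:`detect_well_interior` — a geodesic active contour shrinks from the
   frame border onto the high-gradient well rim; everything outside is
   ignored (a circular Hough fallback is available).
2. :func:`correct_illumination` — a smooth background field estimated from
   reconstruction-based morphological envelopes (the top-hat/bottom-hat
   pair) removes shading multiplicatively, followed by homomorphic filtering
   (log-domain Gaussian high-pass) to attenuate residual multiplicative
   gradients.
3. :func:`enhance_contrast` — monotone log-domain dynamic-range compression
   followed by CLAHE.
4. :func:`detect_spheres` — spheres read as patches of raised local Shannon
   entropy; the entropy map is Otsu-thresholded inside the well, region
   extent is refined against a small-window local-deviation map, and
   touching spheres are separated by watershed seeded from smoothed
   distance-transform maxima.  Regions touching the well contour are
   discarded.
5. :func:`filter_spheres` — spheres are objects with circle-equivalent
   diameter strictly greater than 50 µm and moment-ellipse eccentricity
   strictly less than 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure, morphology, transform, util
from skimage.feature import canny
from skimage.filters import gaussian, threshold_otsu
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import disk
from skimage.segmentation import (inverse_gaussian_gradient,
                                  morphological_geodesic_active_contour,
                                  watershed)

from .frames import IntensityFrame

__all__ = [
    "WellMask",
    "SphereCandidate",
    "SphereRecord",
    "SphereSummary",
    "WellDetectionError",
    "detect_well_interior",
    "correct_illumination",
    "enhance_contrast",
    "detect_spheres",
    "filter_spheres",
    "summarize_well",
    "analyze_well",
]


class WellDetectionError(RuntimeError):
    """Raised when the well rim cannot be located."""


@dataclass
class WellMask:
    """The usable well interior and its bounding contour."""

    interior: np.ndarray  # boolean mask, single connected region
    contour: np.ndarray  # (n, 2) ordered (row, col) path along the rim


@dataclass
class SphereCandidate:
    """A detected region in pixel units, before physical filtering."""

    label: int
    centroid: tuple[float, float]  # (row, col) pixels
    area_px: int
    equivalent_diameter_px: float
    eccentricity: float


@dataclass
class SphereRecord:
    """One sphere passing the size/shape filter, in physical units."""

    sphere_id: int
    centroid: tuple[float, float]  # (row, col) pixels
    area: float  # µm²
    equivalent_diameter: float  # µm, 2·sqrt(area/π)
    eccentricity: float


@dataclass
class SphereSummary:
    """Count and projected-area distribution of the spheres in one well."""

    well_id: str
    sphere_count: int
    areas: list[float]  # µm²
    large_sphere_count: int = 0
    large_area_threshold: float = 1e5  # µm²


# ---------------------------------------------------------------------------
# well interior
# ---------------------------------------------------------------------------


def _hough_well(image: np.ndarray) -> np.ndarray:
    """Fallback rim detection via a circular Hough transform."""
    edges = canny(image, sigma=3)
    nr, nc = image.shape
    radii = np.arange(int(0.25 * min(nr, nc)), int(0.55 * min(nr, nc)), 4)
    h = transform.hough_circle(edges, radii)
    _, cols, rows, rads = transform.hough_circle_peaks(h, radii, total_num_peaks=1)
    if len(rads) == 0:
        raise WellDetectionError("Hough fallback found no circular rim")
    rr, cc = np.ogrid[:nr, :nc]
    return (rr - rows[0]) ** 2 + (cc - cols[0]) ** 2 <= rads[0] ** 2


def detect_well_interior(image: IntensityFrame, max_iterations: int = 500,
                         smoothing: int = 1, gradient_sigma: float = 3.0,
                         balloon_threshold: float = 0.6,
                         fallback: str | None = None) -> WellMask:
    """Locate the well interior with a shrinking geodesic active contour.

    The contour is initialised as a disc inset from the frame border and
    driven inward by a balloon force that is released at high-gradient
    structure, i.e. the well rim.  Convergence is declared when the level
    set stops changing; failure raises :class:`WellDetectionError` unless
    ``fallback='hough'`` enables the circular Hough mask.
    """
    pix = np.asarray(image.pixels, dtype=np.float64)
    lo, hi = pix.min(), pix.max()
    norm = (pix - lo) / (hi - lo) if hi > lo else np.zeros_like(pix)
    gimage = inverse_gaussian_gradient(norm, alpha=100.0, sigma=gradient_sigma)

    nr, nc = norm.shape
    rr, cc = np.ogrid[:nr, :nc]
    r0 = min(nr, nc) / 2.0 - 3.0
    init = ((rr - (nr - 1) / 2.0) ** 2 + (cc - (nc - 1) / 2.0) ** 2
            <= r0 ** 2).astype(np.int8)

    level = init
    converged = False
    chunk = 25
    for _ in range(max(max_iterations // chunk, 1)):
        new = morphological_geodesic_active_contour(
            gimage, num_iter=chunk, init_level_set=level,
            smoothing=smoothing, balloon=-1, threshold=balloon_threshold)
        if np.array_equal(new, level):
            converged = True
            break
        level = new
    if not converged:
        if fallback == "hough":
            interior = _hough_well(norm)
        else:
            raise WellDetectionError(
                f"active contour did not converge within {max_iterations} "
                "iterations (no rim found?); consider fallback='hough'")
    else:
        interior = level.astype(bool)

    interior = ndi.binary_fill_holes(interior)
    labels, n = ndi.label(interior)
    if n == 0:
        raise WellDetectionError("active contour collapsed to an empty region")
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        interior = labels == (1 + int(np.argmax(sizes)))

    contours = measure.find_contours(interior.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return WellMask(interior=interior, contour=contour)


# ---------------------------------------------------------------------------
# illumination correction and enhancement
# ---------------------------------------------------------------------------


def _reconstruction_envelopes(img: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Opening- and closing-by-reconstruction envelopes of the image."""
    eroded = ndi.grey_erosion(img, size=(size, size))
    opened = morphology.reconstruction(eroded, img, method="dilation")
    dilated = ndi.grey_dilation(img, size=(size, size))
    closed = morphology.reconstruction(dilated, img, method="erosion")
    return opened, closed


def correct_illumination(image: IntensityFrame, well: WellMask,
                         max_sphere_diameter: float = 300.0,
                         homomorphic_sigma_factor: float = 1.0,
                         eps: float = 1e-6) -> IntensityFrame:
    """Remove uneven illumination inside the well.

    Illumination is multiplicative, so the whole correction runs in the
    log-intensity domain where it becomes additive.  A smooth background
    field is estimated there as the mean of the opening-by-reconstruction
    and closing-by-reconstruction envelopes (the reconstruction-based
    top-hat/bottom-hat pair) computed with a structuring element larger
    than the largest expected sphere (``max_sphere_diameter`` µm), so
    spheres never leak into the estimate and local texture amplitude is
    left position-independent.  Subtracting the field flat-fields the
    image; homomorphic filtering — a Gaussian high-pass in the same log
    domain — then attenuates any residual gradient.  The result is mapped
    back through exp so the background level reads 1.0 regardless of the
    scene's mean illumination; pixels outside the well are zeroed.
    """
    if not well.interior.any():
        raise ValueError("well interior is empty")
    img = np.asarray(image.pixels, dtype=np.float64)
    se_px = int(np.ceil(max_sphere_diameter / image.pixel_size)) | 1
    if se_px >= min(img.shape):
        raise ValueError("structuring element larger than the image; check "
                         "max_sphere_diameter or pixel_size")
    y = np.log(np.clip(img, eps, None))
    opened, closed = _reconstruction_envelopes(y, se_px)
    background = 0.5 * (opened + closed)
    detail = y - background  # ~0 on background, log-texture on spheres

    # homomorphic high-pass on the flattened log image; the output is
    # normalised so the background level maps to 1.0 regardless of the
    # scene's mean illumination
    sigma = homomorphic_sigma_factor * max_sphere_diameter / image.pixel_size
    low = gaussian(detail, sigma=sigma, preserve_range=True)
    out = np.exp(detail - low)
    out[~well.interior] = 0.0
    return IntensityFrame(out, image.pixel_size)


def enhance_contrast(image: IntensityFrame, compression_gain: float = 3.0,
                     clahe_clip: float = 0.02,
                     clahe_tiles: int = 8) -> IntensityFrame:
    """Dynamic-range compression followed by CLAHE, rescaled to [0, 1].

    The compression is a monotone log-domain mapping
    ``log1p(g·x)/log1p(g)`` applied to the [0, 1]-rescaled image; being
    strictly monotone it preserves the rank (phase) structure of the image
    while compressing highlights.  CLAHE then equalises local contrast.
    A constant image is returned unchanged.
    """
    img = np.asarray(image.pixels, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return IntensityFrame(img.copy(), image.pixel_size)
    x = (img - lo) / (hi - lo)
    y = np.log1p(compression_gain * x) / np.log1p(compression_gain)
    kernel = max(min(img.shape) // clahe_tiles, 8)
    z = exposure.equalize_adapthist(y, kernel_size=kernel,
                                    clip_limit=clahe_clip)
    zl, zh = z.min(), z.max()
    z = (z - zl) / (zh - zl) if zh > zl else z
    return IntensityFrame(z, image.pixel_size)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _local_std(img: np.ndarray, size: int) -> np.ndarray:
    m = ndi.uniform_filter(img, size=size)
    m2 = ndi.uniform_filter(img * img, size=size)
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def detect_spheres(image: IntensityFrame, well: WellMask,
                   entropy_radius: int = 12, fine_window: int = 3,
                   watershed_sigma: float = 4.0, h_min: float = 2.0,
                   boundary_margin: int = 8,
                   min_region_px: int = 30) -> list[SphereCandidate]:
    """Detect candidate sphere regions inside the well.

    Local Shannon entropy in a sliding disc window flags textured patches;
    the Otsu-thresholded entropy map provides detection cores, whose extent
    is refined against a small-window local-standard-deviation map (the
    entropy window dilates object outlines by roughly its own radius, so the
    coarse map is used only to decide *which* fine-texture components are
    spheres, not their geometry).  Touching spheres are separated by
    watershed on the smoothed distance transform with h-maxima seed
    suppression; regions within ``boundary_margin`` pixels of the well
    contour are discarded as partially imaged.
    """
    if not well.interior.any():
        raise ValueError("well interior is empty")
    img = np.clip(np.asarray(image.pixels, dtype=np.float64), 0.0, 1.0)
    img8 = util.img_as_ubyte(img)

    # work strictly inside the boundary band: the corrected image steps to
    # zero at the interior edge, which would otherwise read as texture
    interior = well.interior
    inner = ndi.binary_erosion(interior, structure=disk(boundary_margin))
    if not inner.any():
        raise ValueError("well interior vanishes inside the boundary margin")
    ent = rank_entropy(img8, disk(entropy_radius), mask=interior)
    ent_vals = ent[inner]
    if ent_vals.max() - ent_vals.min() < 1e-12:
        return []
    coarse = (ent > threshold_otsu(ent_vals)) & inner

    std = _local_std(img, fine_window)
    std_vals = std[inner]
    if std_vals.max() - std_vals.min() < 1e-12:
        return []
    fine = (std > threshold_otsu(std_vals)) & inner
    fine = ndi.binary_closing(fine, structure=disk(2))
    fine = ndi.binary_fill_holes(fine)

    # keep fine-texture components that contain an entropy detection core
    labels_fine, n_fine = ndi.label(fine)
    if n_fine == 0:
        return []
    core_hits = ndi.sum_labels(coarse.astype(np.float64), labels_fine,
                               range(1, n_fine + 1))
    sizes = ndi.sum_labels(np.ones_like(labels_fine), labels_fine,
                           range(1, n_fine + 1))
    keep = np.zeros(n_fine + 1, dtype=bool)
    keep[1:] = (core_hits > 0.3 * sizes) & (sizes >= min_region_px)
    refined = keep[labels_fine]

    # offset the half-window dilation bias of the local-deviation map
    refined = ndi.binary_erosion(refined, structure=disk(max(fine_window // 2, 1)))
    refined = morphology.remove_small_objects(refined, max_size=min_region_px - 1)
    if not refined.any():
        return []

    # watershed separation of touching spheres
    dist = ndi.distance_transform_edt(refined)
    smooth = gaussian(dist, sigma=watershed_sigma, preserve_range=True)
    peaks = morphology.h_maxima(smooth, h_min)
    markers, n_seeds = ndi.label(peaks)
    if n_seeds == 0:
        markers, _ = ndi.label(refined)
    labels = watershed(-smooth, markers, mask=refined)

    # discard partially imaged regions truncated at the boundary band
    band = inner & ~ndi.binary_erosion(inner, structure=disk(3))
    drop = set(np.unique(labels[band])) - {0}

    out = []
    for rp in measure.regionprops(labels):
        if rp.label in drop or rp.area < min_region_px:
            continue
        out.append(SphereCandidate(
            label=int(rp.label),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            area_px=int(rp.area),
            equivalent_diameter_px=float(rp.equivalent_diameter_area),
            eccentricity=float(rp.eccentricity),
        ))
    return out


def filter_spheres(candidates: list[SphereCandidate], pixel_size: float,
                   min_diameter: float = 50.0,
                   max_eccentricity: float = 0.8) -> list[SphereRecord]:
    """Keep candidates that qualify as spheres, in physical units.

    A sphere has circle-equivalent diameter strictly greater than
    ``min_diameter`` µm and moment-ellipse eccentricity strictly less than
    ``max_eccentricity``.
    """
    if not pixel_size or pixel_size <= 0:
        raise ValueError("a positive pixel_size (µm/pixel) is required")
    records = []
    for cand in candidates:
        area = cand.area_px * pixel_size ** 2
        diameter = 2.0 * np.sqrt(area / np.pi)
        if diameter > min_diameter and cand.eccentricity < max_eccentricity:
            records.append(SphereRecord(
                sphere_id=len(records) + 1,
                centroid=cand.centroid,
                area=area,
                equivalent_diameter=diameter,
                eccentricity=cand.eccentricity,
            ))
    return records


def summarize_well(records: list[SphereRecord], well_id: str = "",
                   large_area_threshold: float = 1e5) -> SphereSummary:
    """Sphere count and projected-area distribution for one well.

    ``large_sphere_count`` counts spheres with projected area strictly
    greater than ``large_area_threshold`` µm² (default 1×10⁵ µm²).
    """
    areas = [r.area for r in records]
    return SphereSummary(
        well_id=well_id,
        sphere_count=len(records),
        areas=areas,
        large_sphere_count=sum(a > large_area_threshold for a in areas),
        large_area_threshold=large_area_threshold,
    )


def analyze_well(image: IntensityFrame, well_id: str = "",
                 min_diameter: float = 50.0, max_eccentricity: float = 0.8,
                 max_sphere_diameter: float = 300.0,
                 entropy_radius: int = 12, watershed_sigma: float = 4.0,
                 h_min: float = 2.0, fallback: str | None = None,
                 ) -> tuple[WellMask, list[SphereRecord], SphereSummary]:
    """Full per-well chain: rim → correction → enhancement → detection → filter."""
    well = detect_well_interior(image, fallback=fallback)
    corrected = correct_illumination(image, well,
                                     max_sphere_diameter=max_sphere_diameter)
    enhanced = enhance_contrast(corrected)
    candidates = detect_spheres(enhanced, well, entropy_radius=entropy_radius,
                                watershed_sigma=watershed_sigma, h_min=h_min)
    records = filter_spheres(candidates, image.pixel_size,
                             min_diameter=min_diameter,
                             max_eccentricity=max_eccentricity)
    return well, records, summarize_well(records, well_id)
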