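"""Synthetic microscopy scenes and viability tables with exact ground truth.

Each generator emulates one class of input the analysis stages consume:

* :func:`make_fluorescence_frames` — three-channel immunofluorescence scenes
  (DAPI / phalloidin / marker) built from disc-within-disc cells whose
  compartment masks and mean marker intensities are known exactly.
* :func:`make_sabgal_image` — RGB brightfield scenes of cells carrying a
  contiguous histochemically stained sub-region of known hue and area.
* :func:`make_well_image` — a stitched whole-well brightfield scene with
  textured elliptical spheres, a dark well rim, multiplicative illumination
  gradient and vignetting.
* :func:`make_viability_table` — replicate metabolic-activity fractions for a
  two-agent combination under Bliss-independent, synergistic or antagonistic
  truth.

All generators are deterministic given their spec (which embeds the seed);
the returned ground truth is computed from the same geometry used to render,
never re-estimated from the rendered image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .frames import ColorFrame, IntensityFrame

__all__ = [
    "SyntheticDataError",
    "FluorFramesSpec",
    "FluorScene",
    "make_fluorescence_frames",
    "SabgalImageSpec",
    "SabgalScene",
    "make_sabgal_image",
    "SphereSpec",
    "WellImageSpec",
    "WellScene",
    "make_well_image",
    "random_sphere_layout",
    "ViabilitySimSpec",
    "make_viability_table",
    "make_viability_series",
]


class SyntheticDataError(ValueError):
    """Raised when a generator spec is invalid or cannot be realised."""


# ---------------------------------------------------------------------------
# fluorescence frames
# ---------------------------------------------------------------------------


@dataclass
class FluorFramesSpec:
    """Geometry, intensity and noise parameters for a fluorescence scene.

    Cells are discs of radius ``cytoplasm_radius`` with a concentric nuclear
    disc of radius ``nuclear_radius``; centres are placed by rejection
    sampling so that cell footprints keep at least ``clearance`` µm of free
    background between them (which also keeps morphological closing with the
    default 6 µm element from bridging neighbouring cells).
    """

    frame_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # µm / pixel
    n_cells: int = 12
    nuclear_radius: float = 8.0  # µm
    cytoplasm_radius: float = 15.0  # µm
    nuclear_marker_mean: float = 200.0  # a.u.
    cytoplasm_marker_mean: float = 100.0  # a.u.
    background_mean: float = 10.0  # a.u.
    noise_sd: float = 0.0  # a.u., additive Gaussian
    dapi_level: float = 200.0  # a.u. over nuclei
    phalloidin_level: float = 150.0  # a.u. over the cell footprint
    clearance: float = 14.0  # µm of background guaranteed between cells
    seed: int = 0

    def validate(self) -> None:
        if not self.nuclear_radius < self.cytoplasm_radius:
            raise SyntheticDataError("nuclear_radius must be < cytoplasm_radius")
        for name in ("nuclear_marker_mean", "cytoplasm_marker_mean",
                     "background_mean", "dapi_level", "phalloidin_level"):
            if getattr(self, name) < 0:
                raise SyntheticDataError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise SyntheticDataError("n_cells must be >= 0")
        if self.pixel_size <= 0:
            raise SyntheticDataError("pixel_size must be > 0")


@dataclass
class FluorScene:
    """A rendered fluorescence scene plus its exact ground truth."""

    dapi: IntensityFrame
    phalloidin: IntensityFrame
    marker: IntensityFrame
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    nuclear_marker_mean: float
    cytoplasm_marker_mean: float
    centers: np.ndarray  # (n, 2) cell centres in pixel coordinates


def _place_discs(rng: np.random.Generator, shape: tuple[int, int], n: int,
                 radius_px: float, min_center_dist_px: float,
                 margin_px: float, max_attempts_per_disc: int = 400) -> np.ndarray:
    """Rejection-sample ``n`` disc centres with pairwise separation."""
    lo_r, hi_r = margin_px, shape[0] - 1 - margin_px
    lo_c, hi_c = margin_px, shape[1] - 1 - margin_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise SyntheticDataError("frame too small for the requested disc radius")
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_disc * max(n, 1)
    while len(centers) < n:
        if attempts >= budget:
            raise SyntheticDataError(
                f"could only place {len(centers)}/{n} cells after {attempts} "
                "attempts; spec is over-dense")
        attempts += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_center_dist_px ** 2
               for pr, pc in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _disc_mask(shape: tuple[int, int], centers: np.ndarray,
               radius_px: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for r, c in centers:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius_px ** 2
    return mask


def make_fluorescence_frames(spec: FluorFramesSpec) -> FluorScene:
    """Render a three-channel fluorescence scene with exact truth masks.

    The DAPI channel is bright only over nuclear discs, phalloidin over the
    full cell footprint, and the marker channel takes its nuclear and
    cytoplasmic means exactly on the corresponding truth masks before
    additive Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size
    cyt_px = spec.cytoplasm_radius / ps
    nuc_px = spec.nuclear_radius / ps
    min_dist_px = (2 * spec.cytoplasm_radius + spec.clearance) / ps
    # keep the border clearance too, so frame-edge padding cannot interact
    # with morphological closing of near-border cells downstream
    centers = _place_discs(rng, spec.frame_shape, spec.n_cells, cyt_px,
                           min_dist_px, margin_px=cyt_px + spec.clearance / ps)

    nuclear = _disc_mask(spec.frame_shape, centers, nuc_px)
    cell = _disc_mask(spec.frame_shape, centers, cyt_px)
    cytoplasm = cell & ~nuclear

    def render(fg_masks_levels: list[tuple[np.ndarray, float]]) -> np.ndarray:
        img = np.full(spec.frame_shape, spec.background_mean, dtype=np.float64)
        for m, level in fg_masks_levels:
            img[m] = level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=spec.frame_shape)
        return np.clip(img, 0.0, None)

    dapi = render([(nuclear, spec.dapi_level)])
    phall = render([(cell, spec.phalloidin_level)])
    marker = render([(nuclear, spec.nuclear_marker_mean),
                     (cytoplasm, spec.cytoplasm_marker_mean)])

    return FluorScene(
        dapi=IntensityFrame(dapi, ps),
        phalloidin=IntensityFrame(phall, ps),
        marker=IntensityFrame(marker, ps),
        nuclear_mask=nuclear,
        cytoplasm_mask=cytoplasm,
        nuclear_marker_mean=spec.nuclear_marker_mean,
        cytoplasm_marker_mean=spec.cytoplasm_marker_mean,
        centers=centers,
    )


# ---------------------------------------------------------------------------
# SAβGal RGB scenes
# ---------------------------------------------------------------------------


@dataclass
class SabgalImageSpec:
    """Parameters for an RGB histochemistry scene.

    ``cell_regions`` is a list of ``(row_um, col_um, radius_um)`` discs; when
    ``None``, ``n_cells`` non-overlapping discs of radius ``cell_radius`` are
    placed by rejection sampling.  Within each cell a contiguous sub-region
    of ``round(stained_fraction * area)`` pixels is painted at
    ``stained_hue``; the remainder at ``unstained_hue``.  The background is
    near-achromatic and brighter than the cells so that gradient-based
    segmentation has an edge to find.
    """

    frame_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # µm / pixel
    cell_regions: list[tuple[float, float, float]] | None = None
    n_cells: int = 6
    cell_radius: float = 20.0  # µm
    stained_fraction: float = 0.5
    stained_hue: float = 0.42  # HSV hue in [0, 1]
    unstained_hue: float = 0.08
    saturation: float = 0.75
    cell_value: float = 0.70  # HSV value inside cells
    background_value: float = 0.92
    noise_sd: float = 0.0  # additive RGB noise
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise SyntheticDataError("stained_fraction must lie in [0, 1]")
        for name in ("stained_hue", "unstained_hue", "saturation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SyntheticDataError(f"{name} must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise SyntheticDataError("pixel_size must be > 0")


@dataclass
class SabgalScene:
    """A rendered RGB histochemistry scene plus exact truth masks."""

    frame: ColorFrame
    truth_positive_fraction: float
    cell_mask: np.ndarray
    positive_mask: np.ndarray


def _paint_contiguous(cell_mask_single: np.ndarray, k: int) -> np.ndarray:
    """Select a contiguous ``k``-pixel sub-region of one cell mask.

    Pixels are ranked by Euclidean distance from the cell's western boundary
    pixel; for a convex region the first ``k`` pixels form the intersection
    with a disc about that anchor, hence a contiguous patch.
    """
    coords = np.argwhere(cell_mask_single)
    if k <= 0:
        return np.zeros_like(cell_mask_single)
    anchor = coords[np.lexsort((coords[:, 0], coords[:, 1]))][0]
    d2 = ((coords - anchor) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 1], coords[:, 0], d2))
    chosen = coords[order[:k]]
    out = np.zeros_like(cell_mask_single)
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


def make_sabgal_image(spec: SabgalImageSpec) -> SabgalScene:
    """Render an RGB scene with an exactly known stained-area fraction."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size
    shape = spec.frame_shape

    if spec.cell_regions is None:
        rad_px = spec.cell_radius / ps
        centers = _place_discs(rng, shape, spec.n_cells, rad_px,
                               min_center_dist_px=2 * rad_px + 8.0 / ps,
                               margin_px=rad_px + 2)
        regions = [(r, c, rad_px) for r, c in centers]
    else:
        regions = [(r / ps, c / ps, rad / ps)
                   for r, c, rad in spec.cell_regions]

    cell_mask = np.zeros(shape, dtype=bool)
    positive_mask = np.zeros(shape, dtype=bool)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for r, c, rad in regions:
        single = (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
        single &= ~cell_mask  # guard against accidental overlap
        k = int(round(spec.stained_fraction * int(single.sum())))
        positive_mask |= _paint_contiguous(single, k)
        cell_mask |= single

    n_cell = int(cell_mask.sum())
    n_pos = int(positive_mask.sum())
    truth_fraction = n_pos / n_cell if n_cell else float("nan")

    hsv = np.zeros(shape + (3,), dtype=np.float64)
    hsv[..., 0] = rng.uniform(0.0, 1.0, size=shape)  # background hue irrelevant
    hsv[..., 1] = 0.02
    hsv[..., 2] = spec.background_value
    unstained = cell_mask & ~positive_mask
    hsv[unstained] = (spec.unstained_hue, spec.saturation, spec.cell_value)
    hsv[positive_mask] = (spec.stained_hue, spec.saturation, spec.cell_value)
    rgb = hsv2rgb(hsv)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    return SabgalScene(
        frame=ColorFrame(rgb, ps),
        truth_positive_fraction=truth_fraction,
        cell_mask=cell_mask,
        positive_mask=positive_mask,
    )


# ---------------------------------------------------------------------------
# whole-well brightfield scenes
# ---------------------------------------------------------------------------


@dataclass
class SphereSpec:
    """One synthetic sphere: an ellipse with known equivalent geometry.

    ``diameter`` is the circle-equivalent diameter (2·sqrt(area/π)); the
    semi-axes are derived from it and ``eccentricity`` so that the analytic
    area is π·diameter²/4 regardless of elongation.
    """

    center: tuple[float, float]  # (row_um, col_um) offset from well centre
    diameter: float  # µm, circle-equivalent
    eccentricity: float = 0.0
    orientation: float = 0.0  # radians, major axis vs column axis
    contrast: float = 0.35  # texture amplitude relative to background

    @property
    def semi_axes(self) -> tuple[float, float]:
        q = (1.0 - self.eccentricity ** 2) ** 0.25
        a = self.diameter / (2.0 * q)
        b = self.diameter * q / 2.0
        return a, b

    @property
    def area(self) -> float:
        a, b = self.semi_axes
        return math.pi * a * b


@dataclass
class WellImageSpec:
    """Parameters for a stitched whole-well brightfield scene."""

    well_radius: float = 480.0  # µm
    frame_shape: tuple[int, int] = (560, 560)
    pixel_size: float = 2.0  # µm / pixel
    spheres: list[SphereSpec] = field(default_factory=list)
    illumination_gradient: float = 1.0  # max/min multiplicative factor
    vignetting_strength: float = 0.0  # fraction of fall-off at the corners
    noise_sd: float = 0.01  # additive Gaussian, a.u. on [0, 1] scale
    background_level: float = 0.55  # well interior
    exterior_level: float = 0.12
    rim_level: float = 0.03
    rim_width: float = 8.0  # µm, rim ring just inside well_radius
    rim_margin: float = 20.0  # µm clearance required between spheres and rim
    seed: int = 0

    def validate(self) -> None:
        if self.well_radius <= 0 or self.pixel_size <= 0:
            raise SyntheticDataError("well_radius and pixel_size must be > 0")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise SyntheticDataError("vignetting_strength must lie in [0, 1)")
        if self.illumination_gradient <= 0:
            raise SyntheticDataError("illumination_gradient must be > 0")
        limit = self.well_radius - self.rim_width - self.rim_margin
        for s in self.spheres:
            if s.diameter <= 0:
                raise SyntheticDataError("sphere diameters must be > 0")
            if not 0.0 <= s.eccentricity < 1.0:
                raise SyntheticDataError("eccentricity must lie in [0, 1)")
            a, _ = s.semi_axes
            if math.hypot(*s.center) + a > limit:
                raise SyntheticDataError(
                    f"sphere at {s.center} extends outside the usable well disc")


@dataclass
class SphereTruth:
    """Analytic ground truth for one rendered sphere."""

    centroid: tuple[float, float]  # (row, col) pixels
    area: float  # µm²
    equivalent_diameter: float  # µm
    eccentricity: float


@dataclass
class WellScene:
    """A rendered well image plus analytic sphere ground truth."""

    image: IntensityFrame
    truth: list[SphereTruth]
    well_center: tuple[float, float]  # (row, col) pixels
    well_radius_px: float
    interior_mask: np.ndarray  # usable truth disc, inside the rim ring


def make_well_image(spec: WellImageSpec) -> WellScene:
    """Render a whole-well brightfield scene under uneven illumination.

    Spheres are filled with bounded-amplitude pixel-wise uniform texture so
    that local image entropy genuinely rises inside them; the smooth
    background keeps entropy low.  A multiplicative left-to-right gradient
    and radial vignetting model uneven illumination of the stitched image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size
    nr, nc = spec.frame_shape
    cr, cco = (nr - 1) / 2.0, (nc - 1) / 2.0
    rows, cols = np.mgrid[:nr, :nc].astype(np.float64)
    du = (rows - cr) * ps  # µm offsets from the well centre
    dv = (cols - cco) * ps
    rad = np.hypot(du, dv)

    img = np.where(rad <= spec.well_radius, spec.background_level,
                   spec.exterior_level)
    rim = (rad > spec.well_radius - spec.rim_width) & (rad <= spec.well_radius)
    img[rim] = spec.rim_level

    truth: list[SphereTruth] = []
    for s in spec.spheres:
        a, b = s.semi_axes
        dru = du - s.center[0]
        dcu = dv - s.center[1]
        # rotate into the ellipse frame (major axis along +col at orientation 0)
        x = dcu * math.cos(s.orientation) + dru * math.sin(s.orientation)
        y = -dcu * math.sin(s.orientation) + dru * math.cos(s.orientation)
        inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        texture = s.contrast * (0.3 + 0.7 * rng.uniform(-1.0, 1.0, size=int(inside.sum())))
        img[inside] = spec.background_level + texture
        truth.append(SphereTruth(
            centroid=(cr + s.center[0] / ps, cco + s.center[1] / ps),
            area=s.area,
            equivalent_diameter=s.diameter,
            eccentricity=s.eccentricity,
        ))

    # multiplicative illumination: linear left-to-right gradient + vignetting
    g = spec.illumination_gradient
    shading = 1.0 + (g - 1.0) * cols / max(nc - 1, 1)
    if spec.vignetting_strength > 0:
        rmax = rad.max()
        shading = shading * (1.0 - spec.vignetting_strength * (rad / rmax) ** 2)
    img = img * shading
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    return WellScene(
        image=IntensityFrame(img, ps),
        truth=truth,
        well_center=(cr, cco),
        well_radius_px=spec.well_radius / ps,
        # the dark rim ring is well-wall shadow; the usable interior — what a
        # rim-mapping contour encloses — is the open disc inside it
        interior_mask=rad < spec.well_radius - spec.rim_width,
    )


def random_sphere_layout(seed: int, n: int,
                         diameter_range: tuple[float, float] = (80.0, 160.0),
                         eccentricity: float = 0.0,
                         orientation_random: bool = True,
                         max_center_offset: float = 430.0,
                         separation: float = 30.0,
                         contrast: float = 0.35,
                         extra: list[SphereSpec] | None = None,
                         max_attempts: int = 5000) -> list[SphereSpec]:
    """Rejection-sample ``n`` non-touching spheres inside the usable well.

    Sphere centres stay within ``max_center_offset`` µm of the well centre
    (including the semi-major axis) and any two spheres keep at least
    ``separation`` µm between their bounding circles.  ``extra`` spheres are
    treated as already placed and returned first.
    """
    rng = np.random.default_rng(seed)
    out: list[SphereSpec] = list(extra) if extra else []
    target = len(out) + n
    attempts = 0
    while len(out) < target:
        if attempts >= max_attempts:
            raise SyntheticDataError(
                f"could only place {len(out)}/{target} spheres; "
                "layout is over-dense")
        attempts += 1
        r = max_center_offset * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        center = (r * math.sin(th), r * math.cos(th))
        d = rng.uniform(*diameter_range)
        orient = rng.uniform(0.0, math.pi) if orientation_random else 0.0
        cand = SphereSpec(center=center, diameter=d, eccentricity=eccentricity,
                          orientation=orient, contrast=contrast)
        a, _ = cand.semi_axes
        if math.hypot(*center) + a > max_center_offset:
            continue
        if all(math.hypot(center[0] - o.center[0], center[1] - o.center[1])
               > a + o.semi_axes[0] + separation for o in out):
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# viability tables
# ---------------------------------------------------------------------------

_INTERACTIONS = ("bliss", "synergistic", "antagonistic")


@dataclass
class ViabilitySimSpec:
    """Two-agent viability simulation under a known interaction structure.

    Under Bliss independence the true combination survival is the product of
    the single-agent surviving fractions ``f_a · f_b``; a synergistic truth
    subtracts ``interaction_shift`` from that product (clipped at 0) and an
    antagonistic truth adds it (clipped at 1).  Replicates are drawn with
    relative Gaussian noise of coefficient of variation ``cv``.
    """

    f_a: float = 0.8
    f_b: float = 0.7
    interaction: str = "bliss"
    interaction_shift: float = 0.0
    n_replicates: int = 6
    cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.f_a <= 1.0 and 0.0 <= self.f_b <= 1.0):
            raise SyntheticDataError("f_a and f_b must lie in [0, 1]")
        if self.interaction not in _INTERACTIONS:
            raise SyntheticDataError(
                f"interaction must be one of {_INTERACTIONS}")
        if self.n_replicates < 2:
            raise SyntheticDataError(
                "n_replicates must be >= 2 (downstream tests need variance)")
        if self.cv < 0:
            raise SyntheticDataError("cv must be >= 0")

    @property
    def true_combination(self) -> float:
        base = self.f_a * self.f_b
        if self.interaction == "synergistic":
            return max(base - self.interaction_shift, 0.0)
        if self.interaction == "antagonistic":
            return min(base + self.interaction_shift, 1.0)
        return base


def _draw_group(rng: np.random.Generator, mean: float, cv: float,
                n: int) -> np.ndarray:
    vals = mean * (1.0 + cv * rng.standard_normal(n))
    return np.clip(vals, 0.0, None)


def make_viability_table(spec: ViabilitySimSpec) -> pd.DataFrame:
    """Long-format replicate table with groups {control, A, B, AB}."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = {"control": 1.0, "A": spec.f_a, "B": spec.f_b,
             "AB": spec.true_combination}
    rows = []
    for group, mean in means.items():
        for i, v in enumerate(_draw_group(rng, mean, spec.cv, spec.n_replicates)):
            rows.append({"group": group, "replicate": i, "fraction": v})
    return pd.DataFrame(rows)


def make_viability_series(
    f_a: float,
    doses: list[tuple[str, ViabilitySimSpec]] | dict[str, ViabilitySimSpec],
    n_replicates: int = 6,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-dose table sharing one agent-A group across dose levels.

    ``doses`` maps dose labels to specs supplying ``f_b``, ``interaction`` and
    ``interaction_shift``; ``f_a``, ``n_replicates``, ``cv`` and the seed are
    shared.  Groups are named ``control``, ``A``, ``B:<dose>``, ``AB:<dose>``.
    """
    if isinstance(doses, dict):
        doses = list(doses.items())
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in (("control", 1.0), ("A", f_a)):
        for i, v in enumerate(_draw_group(rng, mean, cv, n_replicates)):
            rows.append({"group": group, "replicate": i, "fraction": v})
    for label, dspec in doses:
        dspec = ViabilitySimSpec(
            f_a=f_a, f_b=dspec.f_b, interaction=dspec.interaction,
            interaction_shift=dspec.interaction_shift,
            n_replicates=n_replicates, cv=cv, seed=dspec.seed)
        dspec.validate()
        for group, mean in ((f"B:{label}", dspec.f_b),
                            (f"AB:{label}", dspec.true_combination)):
            for i, v in enumerate(_draw_group(rng, mean, cv, n_replicates)):
                rows.append({"group": group, "replicate": i, "fraction": v})
    return pd.DataFrame(rows)
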