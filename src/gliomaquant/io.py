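"""Image and table I/O with physical-calibration passthrough.

TIFF/OME-TIFF files are read with tifffile and PNG with imageio.  The pixel
size is taken from OME ``PhysicalSizeX`` metadata or TIFF resolution tags
when present, else from the supplied default; a file with neither raises.
Grayscale data become :class:`~gliomaquant.frames.IntensityFrame`, RGB data
:class:`~gliomaquant.frames.ColorFrame`.  Written grayscale TIFFs are 16-bit
with resolution tags; RGB images are written as 8-bit PNG.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .frames import ColorFrame, IntensityFrame

__all__ = ["read_image", "write_intensity_tiff", "write_rgb_png"]

_UM_PER_CM = 1e4


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from OME metadata or TIFF resolution tags."""
    if tf.ome_metadata:
        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
        if m:
            return float(m.group(1))
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        unit = tags["ResolutionUnit"].value
        if num and den:
            px_per_unit = num / den
            if getattr(unit, "value", unit) == 3:  # centimetre
                return _UM_PER_CM / px_per_unit
            if getattr(unit, "value", unit) == 2:  # inch
                return 2.54 * _UM_PER_CM / px_per_unit
    return None


def read_image(path: str | Path, pixel_size: float | None = None
               ) -> IntensityFrame | ColorFrame:
    """Read a TIFF/OME-TIFF or PNG image into a calibrated frame.

    ``pixel_size`` (µm/pixel) is the fallback when the file carries no
    calibration; metadata, when present, wins.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_ps = _pixel_size_from_tiff(tf)
    elif suffix == ".png":
        data = np.asarray(iio.imread(path))
        meta_ps = None
    else:
        raise ValueError(f"unsupported image format: {path.name}")

    ps = meta_ps if meta_ps is not None else pixel_size
    if ps is None:
        raise ValueError(
            f"{path.name} carries no pixel-size metadata and no default "
            "pixel_size was supplied")

    if data.ndim == 3 and data.shape[-1] == 4:  # drop alpha
        data = data[..., :3]
    if data.ndim == 3 and data.shape[-1] == 3:
        return ColorFrame(data, ps)
    return IntensityFrame(np.asarray(data, dtype=np.float64), ps)


def write_intensity_tiff(path: str | Path, frame: IntensityFrame,
                         scale: float | None = None) -> None:
    """Write a 16-bit grayscale TIFF with resolution tags.

    Float data in [0, 1] are scaled to the full 16-bit range unless an
    explicit ``scale`` (a.u. per full range) is given; integer data are
    written as-is.
    """
    data = frame.pixels
    if not np.issubdtype(data.dtype, np.integer):
        top = scale if scale is not None else max(float(data.max()), 1e-12)
        data = np.clip(np.round(data / top * 65535.0), 0, 65535).astype(np.uint16)
    ppcm = _UM_PER_CM / frame.pixel_size
    tifffile.imwrite(path, data, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER")


def write_rgb_png(path: str | Path, frame: ColorFrame) -> None:
    """Write an RGB frame as 8-bit PNG."""
    data = np.clip(np.round(frame.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)
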