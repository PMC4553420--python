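"""Synthetic microscope fields of view and automated grain counting.

Maize pollen grains are large (80-120 um diameter) and nearly spherical,
which makes them identifiable by size alone in a calibrated digital
microscope image.  This module renders fields of view as 8-bit grayscale
rasters containing bright discs on a dark background, together with the
ground-truth grain list, and counts grains by thresholding, connected
components and an equivalent-diameter size window.

Automated counting is reliable only while grains do not overlap; merged
objects larger than a single grain are apportioned by area and flagged, so
downstream code can see when a count required that fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import CalibrationError, InvalidParameterError, PackingError
from .rng import substream

__all__ = [
    "ImageCalibration",
    "SpotImage",
    "GrainCount",
    "render_spot_image",
    "count_grains",
    "count_to_density",
    "GRAIN_DIAMETER_RANGE_UM",
    "SIZE_WINDOW_UM",
]

#: True maize grain diameter range rendered (um).
GRAIN_DIAMETER_RANGE_UM = (80.0, 120.0)
#: Accepted equivalent-diameter window for a single grain (um); the grain
#: range widened by a margin for one-pixel thresholding effects.
SIZE_WINDOW_UM = (70.0, 130.0)
#: Minimum edge-to-edge clearance between rendered grains (um).
MIN_CLEARANCE_UM = 5.0

_BACKGROUND_LEVEL = 25
_GRAIN_LEVEL = 220


@dataclass(frozen=True)
class ImageCalibration:
    """Mapping between pixels and physical units for one magnification.

    The pixel pitch is derived from the calibrated field-of-view area and
    the sensor raster (area = width_px * height_px * microns_per_px^2), so
    the calibration has a single source of truth.  Defaults give a 1.3
    megapixel sensor with a 5 mm^2 field at 200x or 20 mm^2 at 50x.
    """

    magnification: Literal["50x", "200x"] = "200x"
    field_area_mm2: Optional[float] = None
    image_width_px: int = 1280
    image_height_px: int = 1024

    def __post_init__(self) -> None:
        if self.field_area_mm2 is None:
            area = 5.0 if self.magnification == "200x" else 20.0
            object.__setattr__(self, "field_area_mm2", area)
        if self.field_area_mm2 <= 0:
            raise InvalidParameterError("field_area_mm2 must be > 0")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise InvalidParameterError("image dimensions must be >= 1 px")

    @property
    def microns_per_px(self) -> float:
        area_um2 = self.field_area_mm2 * 1e6
        return float(np.sqrt(area_um2 / (self.image_width_px * self.image_height_px)))

    @property
    def area_cm2(self) -> float:
        return self.field_area_mm2 / 100.0

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in um."""
        mpp = self.microns_per_px
        return (self.image_width_px * mpp, self.image_height_px * mpp)


@dataclass
class SpotImage:
    """One rendered field of view with its ground truth.

    ``truth`` rows are (center_x_um, center_y_um, diameter_um); x runs along
    image width, y along height, origin at the top-left pixel corner.
    """

    pixels: np.ndarray
    calibration: ImageCalibration
    truth: list[tuple[float, float, float]] = dc_field(default_factory=list)

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(self.truth, columns=["center_x_um", "center_y_um", "diameter_um"])


@dataclass
class GrainCount:
    """Result of automated counting on one image."""

    count: int
    overlap_flag: bool
    detected_diameters_um: list[float]


def render_spot_image(
    n_grains: int,
    calibration: ImageCalibration | None = None,
    seed: int = 0,
    truth: Optional[list[tuple[float, float, float]]] = None,
    noise_sd: float = 0.0,
    max_attempts_per_grain: int = 1000,
) -> SpotImage:
    """Render ``n_grains`` non-overlapping pollen grains as bright discs.

    Grain diameters are uniform on 80-120 um; centres are placed by
    rejection sampling with a minimum separation of the sum of radii plus
    5 um, every grain fully inside the image.  Passing ``truth`` renders a
    fixed grain list instead (``n_grains`` is then ignored), which allows
    re-rendering the same physical scene under a different calibration.

    Raises :class:`PackingError` when a grain cannot be placed within
    ``max_attempts_per_grain`` attempts — the requested density is beyond
    what non-overlapping packing permits.
    """
    if n_grains < 0:
        raise InvalidParameterError("n_grains must be >= 0")
    calibration = calibration or ImageCalibration()
    rng = substream(seed, "render")
    width_um, height_um = calibration.extent_um
    if truth is None:
        placed: list[tuple[float, float, float]] = []
        lo, hi = GRAIN_DIAMETER_RANGE_UM
        for i in range(n_grains):
            diameter = rng.uniform(lo, hi)
            r = diameter / 2.0
            if width_um <= 2 * r or height_um <= 2 * r:
                raise PackingError(n_grains, len(placed))
            for _ in range(max_attempts_per_grain):
                cx = rng.uniform(r, width_um - r)
                cy = rng.uniform(r, height_um - r)
                ok = all(
                    (cx - px) ** 2 + (cy - py) ** 2
                    >= (r + pd_ / 2.0 + MIN_CLEARANCE_UM) ** 2
                    for px, py, pd_ in placed
                )
                if ok:
                    placed.append((cx, cy, diameter))
                    break
            else:
                raise PackingError(n_grains, len(placed))
        truth = placed
    pixels = _rasterize(truth, calibration, rng, noise_sd)
    return SpotImage(pixels=pixels, calibration=calibration, truth=list(truth))


def _rasterize(truth, calibration: ImageCalibration,
               rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    mpp = calibration.microns_per_px
    h, w = calibration.image_height_px, calibration.image_width_px
    img = np.full((h, w), float(_BACKGROUND_LEVEL))
    for cx, cy, diameter in truth:
        r = diameter / 2.0
        # bounding box in pixel indices (pixel centre of (i, j) = ((j+.5), (i+.5)) * mpp)
        j0 = max(0, int((cx - r) / mpp) - 1)
        j1 = min(w, int((cx + r) / mpp) + 2)
        i0 = max(0, int((cy - r) / mpp) - 1)
        i1 = min(h, int((cy + r) / mpp) + 2)
        jj = (np.arange(j0, j1) + 0.5) * mpp
        ii = (np.arange(i0, i1) + 0.5) * mpp
        mask = (jj[None, :] - cx) ** 2 + (ii[:, None] - cy) ** 2 <= r * r
        img[i0:i1, j0:j1][mask] = _GRAIN_LEVEL
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def count_grains(
    image: SpotImage,
    calibration: ImageCalibration | None = None,
    threshold: Literal["midpoint", "otsu"] = "midpoint",
) -> GrainCount:
    """Count pollen grains by size in a calibrated image.

    Pipeline: global threshold, connected components, equivalent diameter
    2*sqrt(area/pi) in um.  Objects inside the single-grain window
    (70-130 um) count as one grain; larger objects are merged grains and
    are apportioned as round(area / nominal single-grain area) with the
    overlap flag raised; smaller objects are discarded as debris.
    """
    calibration = calibration or image.calibration
    if calibration is None:
        raise CalibrationError("count_grains requires an ImageCalibration")
    px = np.asarray(image.pixels, dtype=float)
    if px.max() - px.min() < 10:  # blank frame: nothing above background
        return GrainCount(count=0, overlap_flag=False, detected_diameters_um=[])
    if threshold == "otsu":
        thr = float(threshold_otsu(px))
    else:
        thr = 0.5 * (px.min() + px.max())
    labels = measure.label(px > thr, connectivity=2)
    mpp = calibration.microns_per_px
    lo, hi = SIZE_WINDOW_UM
    nominal_area_um2 = np.pi * (100.0 / 2.0) ** 2  # 100 um nominal grain
    count = 0
    overlap = False
    diameters: list[float] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * mpp * mpp
        eq_diameter = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_diameter < lo:
            continue  # debris
        if eq_diameter <= hi:
            count += 1
            diameters.append(float(eq_diameter))
        else:
            count += int(round(area_um2 / nominal_area_um2))
            overlap = True
    return GrainCount(count=count, overlap_flag=overlap, detected_diameters_um=diameters)


def count_to_density(count: int, area_cm2: float) -> float:
    """Convert a grain count in one field of view to pollen/cm^2."""
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    if area_cm2 <= 0:
        raise InvalidParameterError("area_cm2 must be > 0")
    return count / area_cm2
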