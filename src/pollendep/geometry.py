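"""Leaf geometry and microscope spots.

The leaf is modelled as a flat rectangle.  The x axis runs along the leaf
length and is divided into lateral sections of 2.5 cm; the y axis runs
across the leaf width, divided into longitudinal sections of 1.75 cm.  The
default raster is 19 x 5 = 95 cells, the partition used to assign random
sampling points.  The midrib runs the length of the leaf at y = width / 2.

A ``Spot`` is one microscope field of view: a small footprint (about 5 mm^2
at 200x magnification, 20 mm^2 at 50x) centred at a point on the leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .errors import GeometryError, InvalidParameterError

__all__ = ["LeafGeometry", "Spot", "SPOT_AREA_200X_CM2", "SPOT_AREA_50X_CM2"]

#: Calibrated field-of-view areas in cm^2 (5 mm^2 at 200x, 20 mm^2 at 50x).
SPOT_AREA_200X_CM2 = 0.05
SPOT_AREA_50X_CM2 = 0.20

LATERAL_SECTION_CM = 2.5
LONGITUDINAL_SECTION_CM = 1.75


@dataclass(frozen=True)
class LeafGeometry:
    """Rectangular leaf with a raster of sampling sections.

    Defaults describe a 47.5 cm x 8.75 cm maize leaf: 19 lateral sections of
    2.5 cm along the length and 5 longitudinal sections of 1.75 cm across
    the width.
    """

    length_cm: float = 19 * LATERAL_SECTION_CM
    width_cm: float = 5 * LONGITUDINAL_SECTION_CM
    n_lateral_sections: int = 19
    n_longitudinal_sections: int = 5

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise InvalidParameterError("leaf dimensions must be positive")
        if self.n_lateral_sections < 1 or self.n_longitudinal_sections < 1:
            raise InvalidParameterError("raster section counts must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_lateral_sections * self.n_longitudinal_sections

    @property
    def cell_size_cm(self) -> tuple[float, float]:
        return (
            self.length_cm / self.n_lateral_sections,
            self.width_cm / self.n_longitudinal_sections,
        )

    def cell_bounds(self, ix: int, iy: int) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of raster cell (ix, iy)."""
        if not (0 <= ix < self.n_lateral_sections and 0 <= iy < self.n_longitudinal_sections):
            raise GeometryError(f"raster cell ({ix}, {iy}) outside the {self.n_lateral_sections}x{self.n_longitudinal_sections} raster")
        dx, dy = self.cell_size_cm
        return ix * dx, (ix + 1) * dx, iy * dy, (iy + 1) * dy

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        x0, x1, y0, y1 = self.cell_bounds(ix, iy)
        return (0.5 * (x0 + x1), 0.5 * (y0 + y1))

    def cell_of(self, flat_index: int) -> tuple[int, int]:
        """Map a flat cell index (row-major over lateral, longitudinal) to (ix, iy)."""
        if not 0 <= flat_index < self.n_cells:
            raise GeometryError(f"flat cell index {flat_index} outside 0..{self.n_cells - 1}")
        return divmod(flat_index, self.n_longitudinal_sections)

    def iter_cells(self) -> Iterator[tuple[int, int, int]]:
        """Yield (flat_index, ix, iy) for every raster cell."""
        for flat in range(self.n_cells):
            ix, iy = self.cell_of(flat)
            yield flat, ix, iy

    def contains(self, x_cm: float, y_cm: float, inset_cm: float = 0.0) -> bool:
        return (
            inset_cm <= x_cm <= self.length_cm - inset_cm
            and inset_cm <= y_cm <= self.width_cm - inset_cm
        )


@dataclass(frozen=True)
class Spot:
    """One microscope field of view on the leaf.

    The footprint is a disc of area ``area_cm2`` by default; a square
    footprint (side ``sqrt(area_cm2)``) is available because a row of
    consecutive square fields can tile a transect that circular fields of
    the same area cannot.
    """

    x_cm: float
    y_cm: float
    area_cm2: float = SPOT_AREA_200X_CM2
    magnification: Literal["50x", "200x"] = "200x"
    leaf_side: Literal["upper", "lower"] = "upper"
    footprint: Literal["circle", "square"] = "circle"

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise InvalidParameterError("spot area must be positive")

    @property
    def radius_cm(self) -> float:
        """Radius of the circular footprint (circumradius-equivalent for squares)."""
        if self.footprint == "circle":
            return float(np.sqrt(self.area_cm2 / np.pi))
        return float(np.sqrt(self.area_cm2) / 2.0)

    @property
    def diameter_cm(self) -> float:
        return 2.0 * self.radius_cm

    def validate_inside(self, geometry: LeafGeometry, tol_cm: float = 1e-9) -> None:
        """Raise GeometryError unless the footprint lies fully on the leaf."""
        if not geometry.contains(self.x_cm, self.y_cm, inset_cm=self.radius_cm - tol_cm):
            raise GeometryError(
                f"spot at ({self.x_cm:.3f}, {self.y_cm:.3f}) cm with radius "
                f"{self.radius_cm:.3f} cm extends beyond the "
                f"{geometry.length_cm} x {geometry.width_cm} cm leaf"
            )
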