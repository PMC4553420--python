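"""Spot-sampling designs on a leaf.

Five designs are implemented, matching the survey layouts compared on a
single maize leaf:

* ``random_raster`` — 35 spots in distinct, randomly chosen raster cells;
* ``full_transect`` — 38 consecutive fields of view across the leaf width
  at mid-length;
* ``repeated_transects`` — 5 lateral transects spread along the length,
  each with 5 spots (midrib, two mid-leaf positions, both edges);
* ``clusters`` — clusters of spots centred in raster cells with high and
  low pilot densities (default 3 high + 3 low clusters of 5 spots);
* ``structured`` — the derived design combining 3 transects of 5 spots
  with 4 clusters of 3 spots (2 high + 2 low), 27 spots in total.

Cluster placement needs a notion of "areas with high and low pollen
deposition"; a ``PilotScan`` provides it as a ranking of raster cells by a
coarse one-image-per-cell scan (or by true cell-mean intensity, for
evaluation studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleDesignError, InvalidParameterError
from .field import DepositionField, draw_spot_count, spot_mean_intensity
from .geometry import SPOT_AREA_200X_CM2, LeafGeometry, Spot
from .rng import substream

__all__ = [
    "SamplingDesign",
    "PilotScan",
    "random_raster_design",
    "full_transect_design",
    "repeated_transects_design",
    "cluster_design",
    "structured_design",
    "make_design",
    "DESIGN_NAMES",
]

DESIGN_NAMES = (
    "random_raster",
    "full_transect",
    "repeated_transects",
    "clusters",
    "structured",
)

#: Mid-leaf spot positions as fractions of the leaf width.
MID_LEAF_FRACTIONS = (0.30, 0.70)


@dataclass
class SamplingDesign:
    """A named, ordered list of spots plus the provenance that produced it."""

    name: str
    spots: list[Spot]
    provenance: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "design": self.name,
                "spot_index": np.arange(len(self.spots)),
                "x_cm": [s.x_cm for s in self.spots],
                "y_cm": [s.y_cm for s in self.spots],
                "area_cm2": [s.area_cm2 for s in self.spots],
                "magnification": [s.magnification for s in self.spots],
            }
        )


@dataclass
class PilotScan:
    """Per-raster-cell densities and the resulting high-to-low ranking."""

    geometry: LeafGeometry
    densities: np.ndarray  # flat, one value per raster cell
    mode: str = "measured"

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (self.geometry.n_cells,):
            raise InvalidParameterError(
                f"pilot scan needs exactly one density per raster cell "
                f"({self.geometry.n_cells}), got {self.densities.shape}"
            )

    @property
    def ranking(self) -> np.ndarray:
        """Flat cell indices ordered from highest to lowest density.

        Ties broken by cell index, so the ranking is deterministic.
        """
        return np.lexsort((np.arange(self.densities.size), -self.densities))

    @classmethod
    def from_field(
        cls,
        field: DepositionField,
        mode: str = "measured",
        spot_area_cm2: float = SPOT_AREA_200X_CM2,
    ) -> "PilotScan":
        """Scan a field: one deterministic 200x measurement per cell centre
        (``mode='measured'``), or the true cell-mean intensity
        (``mode='truth'``)."""
        geom = field.geometry
        vals = np.empty(geom.n_cells)
        for flat, ix, iy in geom.iter_cells():
            cx, cy = geom.cell_center(ix, iy)
            if mode == "truth":
                x0, x1, y0, y1 = geom.cell_bounds(ix, iy)
                gx = np.linspace(x0, x1, 12)
                gy = np.linspace(y0, y1, 12)
                xx, yy = np.meshgrid(gx, gy, indexing="ij")
                vals[flat] = float(np.mean(field.intensity(xx, yy)))
            elif mode == "measured":
                spot = Spot(cx, cy, area_cm2=spot_area_cm2)
                count = draw_spot_count(field, spot, deterministic=True)
                vals[flat] = count / spot_area_cm2
            else:
                raise InvalidParameterError(f"unknown pilot mode '{mode}'")
        return cls(geometry=geom, densities=vals, mode=mode)


def _spot(x: float, y: float, geometry: LeafGeometry, area: float,
          magnification: str, footprint: str) -> Spot:
    """Build a spot with its centre clamped so the footprint stays on the leaf."""
    s = Spot(0.0, 0.0, area_cm2=area, magnification=magnification, footprint=footprint)
    r = s.radius_cm
    x = float(np.clip(x, r, geometry.length_cm - r))
    y = float(np.clip(y, r, geometry.width_cm - r))
    return Spot(x, y, area_cm2=area, magnification=magnification, footprint=footprint)


def random_raster_design(
    geometry: LeafGeometry | None = None,
    n_points: int = 35,
    seed: int = 0,
    spot_area_cm2: float = SPOT_AREA_200X_CM2,
    footprint: str = "circle",
) -> SamplingDesign:
    """``n_points`` distinct raster cells chosen without replacement, one spot
    uniform-random inside each chosen cell."""
    geometry = geometry or LeafGeometry()
    if n_points > geometry.n_cells:
        raise InfeasibleDesignError(
            f"cannot place {n_points} points in {geometry.n_cells} distinct raster cells"
        )
    rng = substream(seed, "design", "random_raster")
    cells = rng.choice(geometry.n_cells, size=n_points, replace=False)
    radius = Spot(0, 0, area_cm2=spot_area_cm2, footprint=footprint).radius_cm
    spots = []
    for flat in cells:
        ix, iy = geometry.cell_of(int(flat))
        x0, x1, y0, y1 = geometry.cell_bounds(ix, iy)
        # uniform inside the cell, restricted so the footprint stays on the leaf
        lo_x = max(x0, radius)
        hi_x = min(x1, geometry.length_cm - radius)
        lo_y = max(y0, radius)
        hi_y = min(y1, geometry.width_cm - radius)
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        spots.append(Spot(x, y, area_cm2=spot_area_cm2, footprint=footprint))
    return SamplingDesign(
        name="random_raster",
        spots=spots,
        provenance={"n_points": n_points, "seed": seed, "cells": [int(c) for c in cells]},
    )


def full_transect_design(
    geometry: LeafGeometry | None = None,
    n_spots: int = 38,
    spot_area_cm2: float = SPOT_AREA_200X_CM2,
    footprint: str = "circle",
    x_position_cm: Optional[float] = None,
) -> SamplingDesign:
    """One lateral transect of consecutive fields of view at mid-length.

    Spot centres are evenly spaced across the width at spacing
    ``width / n_spots`` (first centre at half a spacing).  With the default
    circular 5 mm^2 footprint the spacing (2.30 mm) is slightly below the
    footprint diameter (2.52 mm), so consecutive images overlap marginally
    and the outermost two overhang the edge; both facts are recorded as
    warnings in the provenance, as is physically the case for a consecutive
    image series.  A square footprint (side 2.24 mm) tiles without overlap.
    """
    geometry = geometry or LeafGeometry()
    if n_spots < 1:
        raise InvalidParameterError("n_spots must be >= 1")
    x = geometry.length_cm / 2 if x_position_cm is None else x_position_cm
    spacing = geometry.width_cm / n_spots
    proto = Spot(0, 0, area_cm2=spot_area_cm2, footprint=footprint)
    warnings = []
    if spacing < proto.diameter_cm:
        warnings.append(
            f"spacing {spacing:.4f} cm < footprint diameter {proto.diameter_cm:.4f} cm: "
            "consecutive images overlap"
        )
    spots = [
        Spot((x), (k + 0.5) * spacing, area_cm2=spot_area_cm2,
             footprint=footprint)
        for k in range(n_spots)
    ]
    if spots and spots[0].y_cm < proto.radius_cm:
        warnings.append("outermost footprints overhang the leaf edge")
    return SamplingDesign(
        name="full_transect",
        spots=spots,
        provenance={"n_spots": n_spots, "x_cm": x, "spacing_cm": spacing,
                    "warnings": warnings},
    )


def _transect_y_positions(geometry: LeafGeometry, radius: float) -> list[float]:
    """The five per-transect y positions: edge, mid-leaf, midrib, mid-leaf, edge."""
    w = geometry.width_cm
    return [
        radius,                       # near edge (inset = half spot diameter)
        MID_LEAF_FRACTIONS[0] * w,    # mid leaf
        0.5 * w,                      # midrib
        MID_LEAF_FRACTIONS[1] * w,    # mid leaf
        w - radius,                   # far edge
    ]


def repeated_transects_design(
    geometry: LeafGeometry | None = None,
    n_transects: int = 5,
    spot_area_cm2: float = SPOT_AREA_200X_CM2,
    footprint: str = "circle",
    name: str = "repeated_transects",
) -> SamplingDesign:
    """``n_transects`` lateral transects evenly spread along the leaf length,
    each with 5 spots: midrib, two mid-leaf spots (30% / 70% of width) and
    both edges.  Transect x positions sit at fractions (2i+1)/(2n) of the
    length (0.1, 0.3, 0.5, 0.7, 0.9 for the default n = 5)."""
    geometry = geometry or LeafGeometry()
    if n_transects < 1:
        raise InvalidParameterError("n_transects must be >= 1")
    proto = Spot(0, 0, area_cm2=spot_area_cm2, footprint=footprint)
    ys = _transect_y_positions(geometry, proto.radius_cm)
    xs = [(2 * i + 1) / (2 * n_transects) * geometry.length_cm for i in range(n_transects)]
    spots = [
        Spot(x, y, area_cm2=spot_area_cm2, footprint=footprint)
        for x in xs for y in ys
    ]
    return SamplingDesign(
        name=name,
        spots=spots,
        provenance={"n_transects": n_transects, "x_positions_cm": xs,
                    "y_positions_cm": ys},
    )


def _sample_extreme_cells(pilot: PilotScan, n: int, which: str,
                          rng: np.random.Generator,
                          exclude: Sequence[int] = ()) -> list[int]:
    geometry = pilot.geometry
    decile = max(1, int(np.ceil(0.1 * geometry.n_cells)))
    ranking = pilot.ranking
    pool = ranking[:decile] if which == "high" else ranking[-decile:]
    pool = np.array([c for c in pool if c not in set(exclude)])
    if len(pool) < n:
        raise InfeasibleDesignError(
            f"need {n} distinct {which}-density cells but only {len(pool)} "
            f"available in the {which} decile"
        )
    return [int(c) for c in rng.choice(pool, size=n, replace=False)]


def cluster_design(
    geometry: LeafGeometry | None = None,
    pilot: PilotScan | None = None,
    n_high: int = 3,
    n_low: int = 3,
    points_per_cluster: int = 5,
    seed: int = 0,
    cluster_radius_cm: float = 1.0,
    spot_area_cm2: float = SPOT_AREA_200X_CM2,
    footprint: str = "circle",
    name: str = "clusters",
) -> SamplingDesign:
    """Clusters of spots in high- and low-deposition areas.

    High (low) cluster centres are drawn from distinct raster cells in the
    top (bottom) decile of the pilot ranking; each cluster places
    ``points_per_cluster`` spots uniformly within ``cluster_radius_cm`` of
    its cell centre.  The default 3 + 3 clusters of 5 give 30 spots.
    """
    geometry = geometry or LeafGeometry()
    if pilot is None:
        raise InfeasibleDesignError("cluster design requires a pilot scan")
    if n_high < 0 or n_low < 0 or points_per_cluster < 0:
        raise InvalidParameterError("cluster counts must be >= 0")
    rng = substream(seed, "design", name)
    high_cells = _sample_extreme_cells(pilot, n_high, "high", rng)
    low_cells = _sample_extreme_cells(pilot, n_low, "low", rng, exclude=high_cells)
    proto = Spot(0, 0, area_cm2=spot_area_cm2, footprint=footprint)
    spots: list[Spot] = []
    labels: list[str] = []
    for kind, cells in (("high", high_cells), ("low", low_cells)):
        for flat in cells:
            cx, cy = geometry.cell_center(*geometry.cell_of(flat))
            for _ in range(points_per_cluster):
                # uniform in the disc around the cluster centre
                u, theta = rng.uniform(), rng.uniform(0, 2 * np.pi)
                rr = cluster_radius_cm * np.sqrt(u)
                spots.append(_spot(cx + rr * np.cos(theta), cy + rr * np.sin(theta),
                                   geometry, spot_area_cm2, proto.magnification,
                                   footprint))
                labels.append(kind)
    spots, jittered = _resolve_collisions(spots, geometry, rng)
    return SamplingDesign(
        name=name,
        spots=spots,
        provenance={
            "n_high": n_high, "n_low": n_low,
            "points_per_cluster": points_per_cluster, "seed": seed,
            "high_cells": high_cells, "low_cells": low_cells,
            "cluster_kind": labels, "pilot_mode": pilot.mode,
            "jittered_spots": jittered,
        },
    )


def _resolve_collisions(spots: list[Spot], geometry: LeafGeometry,
                        rng: np.random.Generator,
                        max_rounds: int = 20) -> tuple[list[Spot], list[int]]:
    """Jitter spots that sit closer than one footprint diameter to an earlier
    spot by up to half a diameter; returns the indices that moved."""
    out = list(spots)
    jittered: list[int] = []
    for i in range(1, len(out)):
        for _ in range(max_rounds):
            si = out[i]
            d = si.diameter_cm
            close = any(
                (si.x_cm - sj.x_cm) ** 2 + (si.y_cm - sj.y_cm) ** 2 < d * d
                for sj in out[:i]
            )
            if not close:
                break
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(0.5 * d, 1.0 * d)
            moved = _spot(si.x_cm + step * np.cos(ang), si.y_cm + step * np.sin(ang),
                          geometry, si.area_cm2, si.magnification, si.footprint)
            out[i] = moved
            if i not in jittered:
                jittered.append(i)
    return out, jittered


def structured_design(
    geometry: LeafGeometry | None = None,
    pilot: PilotScan | None = None,
    seed: int = 0,
    spot_area_cm2: float = SPOT_AREA_200X_CM2,
    footprint: str = "circle",
) -> SamplingDesign:
    """The derived design: 3 transects of 5 spots + 4 clusters of 3 spots
    (2 high + 2 low), 27 spots in total."""
    geometry = geometry or LeafGeometry()
    transects = repeated_transects_design(
        geometry, n_transects=3, spot_area_cm2=spot_area_cm2, footprint=footprint
    )
    clusters = cluster_design(
        geometry, pilot, n_high=2, n_low=2, points_per_cluster=3, seed=seed,
        spot_area_cm2=spot_area_cm2, footprint=footprint, name="structured_clusters",
    )
    rng = substream(seed, "design", "structured", "jitter")
    spots, jittered = _resolve_collisions(
        transects.spots + clusters.spots, geometry, rng
    )
    return SamplingDesign(
        name="structured",
        spots=spots,
        provenance={
            "seed": seed,
            "transects": transects.provenance,
            "clusters": clusters.provenance,
            "n_transect_spots": len(transects.spots),
            "n_cluster_spots": len(clusters.spots),
            "jittered_spots": jittered,
        },
    )


def make_design(name: str, geometry: LeafGeometry | None = None,
                pilot: PilotScan | None = None, seed: int = 0,
                **kwargs) -> SamplingDesign:
    """Dispatch a design by name with its default parameters."""
    geometry = geometry or LeafGeometry()
    if name == "random_raster":
        return random_raster_design(geometry, seed=seed, **kwargs)
    if name == "full_transect":
        return full_transect_design(geometry, **kwargs)
    if name == "repeated_transects":
        return repeated_transects_design(geometry, **kwargs)
    if name == "clusters":
        return cluster_design(geometry, pilot, seed=seed, **kwargs)
    if name == "structured":
        return structured_design(geometry, pilot, seed=seed, **kwargs)
    raise InvalidParameterError(
        f"unknown design '{name}'; expected one of {DESIGN_NAMES}"
    )
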