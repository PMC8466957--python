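"""Foveal/parafoveal sector grid.

The analysis grid is the one superimposed on en-face angiograms: a foveal
disk of 1 mm diameter centered on the fovea, a parafoveal ring bounded
externally by a 2.9 mm diameter circle, each split into four 90-degree
quadrants.  Quadrant boundaries default to the diagonal (ETDRS-style)
split at 45/135/225/315 degrees so that the sectors are the superior,
nasal, inferior and temporal wedges.

Conventions (chosen to make the partition exact):

* radial intervals are inner-inclusive / outer-exclusive — ``r < 0.5`` is
  foveal, ``0.5 <= r < 1.45`` parafoveal, ``r >= 1.45`` outside;
* angular arcs are half-open ``(a, a + 90]``, so a pixel exactly on a
  boundary angle belongs to the arc ending there.

The quadrant colocalized with tissue loss is the region of interest (ROI);
its neighbours are R1/R2 and the opposite quadrant ((roi + 2) mod 4) is R3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SectorGrid",
    "RegionLabel",
    "build_grid",
    "label_pixel",
    "rasterize_regions",
    "region_table",
    "ZONE_FOVEAL",
    "ZONE_PARAFOVEAL",
    "ZONE_OUTSIDE",
]

ZONE_FOVEAL = 0
ZONE_PARAFOVEAL = 1
ZONE_OUTSIDE = 2

_QUADRANT_NAMES = ("ROI", "R1", "R3", "R2")  # name of (index - roi) mod 4


@dataclass(frozen=True)
class SectorGrid:
    center_mm: tuple[float, float]
    foveal_radius_mm: float = 0.5
    parafoveal_outer_radius_mm: float = 1.45
    rotation_offset_deg: float = 45.0
    roi_quadrant: int | None = None

    def __post_init__(self):
        if not 0 < self.foveal_radius_mm < self.parafoveal_outer_radius_mm:
            raise ValueError("need 0 < foveal radius < parafoveal outer radius")

    @property
    def quadrant_boundaries_deg(self) -> tuple[float, float, float, float]:
        off = self.rotation_offset_deg % 90.0
        return tuple(off + 90.0 * k for k in range(4))

    def quadrant_of_angle(self, angle_deg: float) -> int:
        """Index of the arc ``(b[q-1], b[q]]`` containing ``angle_deg``."""
        start = self.quadrant_boundaries_deg[0] - 90.0
        t = (np.asarray(angle_deg, dtype=float) - start) % 360.0
        t = np.where(t == 0.0, 360.0, t)
        return (np.ceil(t / 90.0).astype(int) - 1) % 4

    def quadrant_name(self, q: int) -> str | int:
        if self.roi_quadrant is None:
            return int(q)
        return _QUADRANT_NAMES[(int(q) - self.roi_quadrant) % 4]


@dataclass(frozen=True)
class RegionLabel:
    zone: str  # "foveal" | "parafoveal" | "outside"
    quadrant: int | str | None  # None outside the grid


def build_grid(
    center_mm: tuple[float, float],
    roi_angle_deg: float | None = None,
    rotation_offset_deg: float = 45.0,
    foveal_radius_mm: float = 0.5,
    parafoveal_outer_radius_mm: float = 1.45,
) -> SectorGrid:
    """Construct the 4+4 sector grid, optionally locating the ROI quadrant.

    ``roi_angle_deg`` is the polar angle (degrees, counter-clockwise from
    +x) of the tissue-loss location; the quadrant containing it becomes the
    ROI.  How that angle is derived from B-scan geometry is an input to the
    pipeline, not something it infers.
    """
    grid = SectorGrid(
        center_mm=tuple(center_mm),
        foveal_radius_mm=foveal_radius_mm,
        parafoveal_outer_radius_mm=parafoveal_outer_radius_mm,
        rotation_offset_deg=rotation_offset_deg,
    )
    if roi_angle_deg is None:
        return grid
    roi = int(grid.quadrant_of_angle(roi_angle_deg))
    return SectorGrid(
        center_mm=grid.center_mm,
        foveal_radius_mm=foveal_radius_mm,
        parafoveal_outer_radius_mm=parafoveal_outer_radius_mm,
        rotation_offset_deg=rotation_offset_deg,
        roi_quadrant=roi,
    )


def label_pixel(grid: SectorGrid, x_mm: float, y_mm: float) -> RegionLabel:
    """Zone and quadrant of a single point (mm, image coordinates)."""
    dx = x_mm - grid.center_mm[0]
    dy = y_mm - grid.center_mm[1]
    r = float(np.hypot(dx, dy))
    if r >= grid.parafoveal_outer_radius_mm:
        return RegionLabel(zone="outside", quadrant=None)
    zone = "foveal" if r < grid.foveal_radius_mm else "parafoveal"
    q = int(grid.quadrant_of_angle(np.degrees(np.arctan2(dy, dx))))
    return RegionLabel(zone=zone, quadrant=grid.quadrant_name(q))


def rasterize_regions(
    grid: SectorGrid, shape_px: tuple[int, int], pixel_pitch_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Label every pixel of a raster with its zone and quadrant.

    Pixel ``(i, j)`` is represented by its center
    ``((j + 0.5) * pitch, (i + 0.5) * pitch)`` mm.  Returns
    ``(zones, quadrants)`` integer rasters; ``quadrants`` is -1 outside the
    grid.  Raises if the outer circle does not fit inside the raster.
    """
    h, w = shape_px
    pitch = pixel_pitch_um / 1000.0
    cx, cy = grid.center_mm
    rad = grid.parafoveal_outer_radius_mm
    if cx - rad < 0 or cy - rad < 0 or cx + rad > w * pitch or cy + rad > h * pitch:
        raise ValueError("sector grid exceeds the raster extent")

    x = (np.arange(w) + 0.5) * pitch - cx
    y = (np.arange(h) + 0.5) * pitch - cy
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)

    zones = np.full(shape_px, ZONE_OUTSIDE, dtype=np.int8)
    zones[r < grid.parafoveal_outer_radius_mm] = ZONE_PARAFOVEAL
    zones[r < grid.foveal_radius_mm] = ZONE_FOVEAL

    quadrants = grid.quadrant_of_angle(np.degrees(np.arctan2(yy, xx))).astype(np.int8)
    quadrants[zones == ZONE_OUTSIDE] = -1
    return zones, quadrants


def region_table(
    zones: np.ndarray, quadrants: np.ndarray, pixel_pitch_um: float, grid: SectorGrid
) -> pd.DataFrame:
    """Pixel counts and areas per (zone, quadrant) sector."""
    px_area = (pixel_pitch_um / 1000.0) ** 2
    rows = []
    for zone_code, zone_name in ((ZONE_FOVEAL, "foveal"), (ZONE_PARAFOVEAL, "parafoveal")):
        for q in range(4):
            n = int(np.count_nonzero((zones == zone_code) & (quadrants == q)))
            rows.append(
                {
                    "zone": zone_name,
                    "quadrant": grid.quadrant_name(q),
                    "pixel_count": n,
                    "area_mm2": n * px_area,
                }
            )
    return pd.DataFrame(rows)
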