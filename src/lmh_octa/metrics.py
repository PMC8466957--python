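"""Vessel/perfusion density and capillary-free-zone (CFZ) morphometry.

The quantities computed here are the per-region OCTA indices reported for
lamellar macular holes: vessel density (VD, percentage of region pixels
classified as vessel), perfusion density (PD, percentage classified as
perfused vessel), and the CFZ shape descriptors area ``A`` (mm^2),
perimeter ``P`` (mm) and circularity ``C = 4*pi*A / P**2``.

Polygons are closed contours given as ``(n, 2)`` arrays of ``[x_mm, y_mm]``
vertices (the closing edge is implicit).  Area and simplicity checks are
delegated to :mod:`shapely`; the perimeter is the plain sum of Euclidean
edge lengths so that degenerate repeated vertices contribute zero length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.validation import explain_validity
from skimage import measure
from skimage.filters import gaussian

__all__ = [
    "CFZMetrics",
    "circularity",
    "polygon_area",
    "polygon_perimeter",
    "vessel_density",
    "perfusion_density",
    "cfz_from_mask",
    "cfz_from_polygon",
    "region_metrics",
]

#: tolerance above 1 allowed for discretized contours before a circularity
#: value is treated as suspicious (isoperimetric inequality allowance)
CIRCULARITY_EPS = 0.02


@dataclass(frozen=True)
class CFZMetrics:
    """CFZ morphometry: area ``A`` (mm^2), perimeter ``P`` (mm), ``4*pi*A/P^2``."""

    area_mm2: float
    perimeter_mm: float
    circularity: float


def _vertices(poly) -> np.ndarray:
    arr = np.asarray(poly, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of [x, y] vertices")
    # drop an explicit closing vertex so edges are not double counted by area
    if np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
        if arr.shape[0] < 3:
            raise ValueError("polygon degenerates to fewer than 3 distinct vertices")
    return arr


def as_shapely(poly) -> _ShapelyPolygon:
    """Validate a vertex array as a simple polygon; raise with the
    self-intersection location otherwise."""
    arr = _vertices(poly)
    sp = _ShapelyPolygon(arr)
    if not sp.is_valid:
        raise ValueError(
            f"polygon is not simple: {explain_validity(sp)}"
        )
    return sp


def polygon_area(poly) -> float:
    """Area of a simple polygon in mm^2 (shoelace, absolute value)."""
    return float(as_shapely(poly).area)


def polygon_perimeter(poly) -> float:
    """Perimeter in mm: Euclidean edge lengths including the closing edge."""
    arr = _vertices(poly)
    closed = np.vstack([arr, arr[:1]])
    return float(np.sum(np.hypot(*(np.diff(closed, axis=0).T))))


def circularity(area_mm2: float, perimeter_mm: float) -> float:
    """Shape circularity ``4*pi*A/P**2``.

    Equals 1 for a circle and approaches 0 as the contour becomes less
    round or less smooth.  Values above ``1 + CIRCULARITY_EPS`` are
    geometrically impossible for a simple closed contour and trigger a
    warning (they indicate a contouring error), but are returned unclamped.
    """
    if perimeter_mm <= 0:
        raise ValueError("perimeter must be positive")
    if area_mm2 < 0:
        raise ValueError("area must be nonnegative")
    c = 4.0 * math.pi * area_mm2 / perimeter_mm**2
    if c > 1.0 + CIRCULARITY_EPS:
        warnings.warn(
            f"circularity {c:.3f} exceeds the isoperimetric bound; "
            "the contour is likely corrupt",
            stacklevel=2,
        )
    return c


def cfz_from_polygon(poly) -> CFZMetrics:
    """Morphometry of a manually contoured CFZ border polygon."""
    a = polygon_area(poly)
    p = polygon_perimeter(poly)
    return CFZMetrics(area_mm2=a, perimeter_mm=p, circularity=circularity(a, p))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _count_in_region(mask: np.ndarray, region: np.ndarray) -> tuple[int, int]:
    mask = np.asarray(mask, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if mask.shape != region.shape:
        raise ValueError("mask and region shapes differ")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("region is empty")
    return int(np.count_nonzero(mask & region)), n_region


def vessel_density(vessel_mask: np.ndarray, region: np.ndarray) -> float:
    """VD in percent: 100 x (vessel pixels in region) / (region pixels)."""
    k, n = _count_in_region(vessel_mask, region)
    return 100.0 * k / n


def perfusion_density(perfusion_mask: np.ndarray, region: np.ndarray) -> float:
    """PD in percent: 100 x (perfused pixels in region) / (region pixels)."""
    k, n = _count_in_region(perfusion_mask, region)
    return 100.0 * k / n


def region_metrics(
    vessel_mask: np.ndarray,
    perfusion_mask: np.ndarray | None,
    zones: np.ndarray,
    quadrants: np.ndarray,
    pixel_pitch_um: float,
) -> pd.DataFrame:
    """Per-sector VD/PD table over the foveal/parafoveal 4+4 grid.

    ``zones``/``quadrants`` are the label rasters from
    :func:`lmh_octa.grid.rasterize_regions`.  Totals are pixel-count
    weighted, i.e. computed on the union region directly.
    """
    px_area_mm2 = (pixel_pitch_um / 1000.0) ** 2
    rows = []

    def _row(zone_name, quad_name, region):
        n = int(region.sum())
        vd = vessel_density(vessel_mask, region)
        pd_ = (
            perfusion_density(perfusion_mask, region)
            if perfusion_mask is not None
            else np.nan
        )
        rows.append(
            {
                "zone": zone_name,
                "quadrant": quad_name,
                "pixel_count": n,
                "area_mm2": n * px_area_mm2,
                "vd_percent": vd,
                "pd_percent": pd_,
            }
        )

    from .grid import ZONE_FOVEAL, ZONE_PARAFOVEAL  # local import, no cycle at load

    for zone_code, zone_name in ((ZONE_FOVEAL, "foveal"), (ZONE_PARAFOVEAL, "parafoveal")):
        in_zone = zones == zone_code
        for q in range(4):
            _row(zone_name, q, in_zone & (quadrants == q))
        _row(zone_name, "total", in_zone)
    _row("all", "total", (zones == ZONE_FOVEAL) | (zones == ZONE_PARAFOVEAL))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CFZ extraction from a binary vessel map (synthetic-test pathway; clinical
# CFZ borders are manual polygons and enter through cfz_from_polygon)
# ---------------------------------------------------------------------------

def cfz_from_mask(
    vessel_mask: np.ndarray,
    seed_point_px: tuple[int, int],
    pixel_pitch_um: float,
    smooth_sigma_px: float = 1.0,
) -> tuple[CFZMetrics, np.ndarray]:
    """Extract the central avascular zone around ``seed_point_px``.

    Flood-fills non-vessel pixels (4-connectivity) from the seed, rejects
    components touching the image border (unbounded zone), then traces a
    sub-pixel boundary by marching squares on a Gaussian-smoothed indicator
    at level 0.5.  Smoothing suppresses the staircase perimeter inflation
    of raw binary contours.  Returns the metrics and the contour polygon in
    mm (pixel-center convention: pixel ``(i, j)`` center at
    ``((j + 0.5) * pitch, (i + 0.5) * pitch)``).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    i0, j0 = (int(round(c)) for c in seed_point_px)
    if vessel_mask[i0, j0]:
        raise ValueError("seed point lies on a vessel pixel")
    avascular = ~vessel_mask
    labels, _ = ndimage.label(avascular)  # default structure = 4-connectivity
    comp = labels == labels[i0, j0]
    if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
        raise ValueError("avascular component touches the image border (unbounded)")

    field = gaussian(comp.astype(float), sigma=smooth_sigma_px, mode="constant")
    contours = measure.find_contours(field, 0.5)
    if not contours:
        raise ValueError("no closed contour found around the seed point")
    contour = max(contours, key=len)  # outermost/longest bounds the zone
    pitch_mm = pixel_pitch_um / 1000.0
    # find_contours yields (row, col) with pixel centers at integer coords
    poly = np.column_stack(
        [(contour[:, 1] + 0.5) * pitch_mm, (contour[:, 0] + 0.5) * pitch_mm]
    )
    return cfz_from_polygon(poly), poly
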