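"""Behrmann equal-area projection and the global analysis grid.

All spatial filtering, gridding and polygon work in this package happens on
the plane of the Behrmann cylindrical equal-area projection (standard
parallel 30°, authalic sphere).  The projection is area-true everywhere,
which is what makes a fixed metric cell size meaningful for assemblage-level
summaries: every cell covers the same ground area regardless of latitude.

Forward equations (lambda, phi in radians)::

    x = R * lambda * cos(30°)
    y = R * sin(phi) / cos(30°)

with R the authalic Earth radius.  Distances measured on this plane are
compressed/stretched relative to the geodesic by at most a few percent below
~60° latitude; the package uses planar distances consistently, including for
the range-proximity filter whose threshold is itself defined as the grid
cell edge length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

#: Authalic (equal-area) sphere radius in metres.
AUTHALIC_RADIUS = 6_371_007.181

#: Standard parallel of the Behrmann projection, degrees.
STD_PARALLEL = 30.0

_COS_SP = np.cos(np.radians(STD_PARALLEL))

#: Edge length of one analysis grid cell, metres (cell area 148,953 km^2).
CELL_SIZE = 385_900.0

#: Maximum allowed distance from a sequence to its species' range, metres.
RANGE_FILTER_MAX_DIST = 385_945.1


def behrmann_forward(lon, lat):
    """Project lon/lat degrees to Behrmann x/y metres.

    Accepts scalars or arrays; raises ``ValueError`` for latitudes outside
    [-90, 90] or longitudes outside [-180, 180].
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    x = AUTHALIC_RADIUS * np.radians(lon) * _COS_SP
    y = AUTHALIC_RADIUS * np.sin(np.radians(lat)) / _COS_SP
    return x, y


def behrmann_inverse(x, y):
    """Inverse projection; y values beyond the pole lines are clipped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / (AUTHALIC_RADIUS * _COS_SP))
    s = np.clip(y * _COS_SP / AUTHALIC_RADIUS, -1.0, 1.0)
    lat = np.degrees(np.arcsin(s))
    return lon, lat


@dataclass(frozen=True)
class GridSpec:
    """Equal-area analysis grid: half-open square cells on the Behrmann plane.

    Cells are indexed by integer ``(col, row)`` with the origin cell having
    its south-west corner at the projected coordinates of (lon 0, lat 0).
    A point lying exactly on a cell boundary belongs to the cell on its
    east/north side (floor convention), so cells partition the plane.
    """

    cell_size: float = CELL_SIZE

    def cell_of(self, lon, lat):
        """Assign lon/lat point(s) to grid cell ids ``(col, row)``."""
        x, y = behrmann_forward(lon, lat)
        col = np.floor(x / self.cell_size).astype(int)
        row = np.floor(y / self.cell_size).astype(int)
        if col.ndim == 0:
            return int(col), int(row)
        return col, row

    def cell_polygon(self, col: int, row: int) -> Polygon:
        """Cell outline as a shapely box in projected metres."""
        cs = self.cell_size
        return box(col * cs, row * cs, (col + 1) * cs, (row + 1) * cs)

    def cell_centroid(self, col: int, row: int) -> tuple[float, float]:
        cs = self.cell_size
        return ((col + 0.5) * cs, (row + 0.5) * cs)


def project_ring(ring) -> np.ndarray:
    """Project a sequence of (lon, lat) vertices to an (n, 2) array of metres."""
    arr = np.asarray(ring, dtype=float)
    x, y = behrmann_forward(arr[:, 0], arr[:, 1])
    return np.column_stack([x, y])
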