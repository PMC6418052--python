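"""Kernel home ranges, movement distances and intraspecific overlap.

The utilization distribution (UD) is a bivariate Gaussian product-kernel
density on a regular grid with the ecology-standard reference ("href")
bandwidth.  Home range and core area are the 95% and 50% isopleths: the
smallest sets of grid cells whose cumulative probability mass reaches the
level, polygonized at cell boundaries so the enclosed mass is exact up to
one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

HOME_RANGE_LEVEL = 95.0
CORE_AREA_LEVEL = 50.0


@dataclass
class UtilizationDistribution:
    x0: float          # west edge of cell column 0
    y0: float          # south edge of cell row 0
    resolution: float
    masses: np.ndarray  # (ny, nx), sums to 1
    bandwidth: float
    individual_id: str = ""

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.masses.shape[1]) + 0.5) * self.resolution

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.masses.shape[0]) + 0.5) * self.resolution


@dataclass
class RangePolygon:
    individual_id: str
    level: float
    polygon: "shapely.Geometry"
    area_m2: float
    enclosed_mass: float


def href_bandwidth(fixes: np.ndarray) -> float:
    """Reference bandwidth h = sigma * n^(-1/6) with pooled per-axis SD."""
    fixes = np.asarray(fixes, dtype=float)
    n = len(fixes)
    sigma = np.sqrt(0.5 * (fixes[:, 0].var(ddof=1) + fixes[:, 1].var(ddof=1)))
    return float(sigma * n ** (-1.0 / 6.0))


def kde_ud(
    fixes: np.ndarray,
    bandwidth: float | None = None,
    resolution: float = 1.0,
    pad_bandwidths: float = 3.0,
    individual_id: str = "",
) -> UtilizationDistribution:
    """Estimate the UD from fixes with a Gaussian product kernel.

    The grid extends ``pad_bandwidths`` bandwidths beyond the fix bounding
    box; cell masses are the kernel density at cell centers times the cell
    area, renormalized to sum to one.
    """
    fixes = np.asarray(fixes, dtype=float)
    if fixes.ndim != 2 or fixes.shape[1] != 2:
        raise ValueError("fixes must be an (n, 2) array")
    if len(fixes) < 5:
        raise ValueError("insufficient fixes: need at least 5")
    h = float(bandwidth) if bandwidth is not None else href_bandwidth(fixes)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    pad = pad_bandwidths * h
    x0 = np.floor((fixes[:, 0].min() - pad) / resolution) * resolution
    y0 = np.floor((fixes[:, 1].min() - pad) / resolution) * resolution
    nx = int(np.ceil((fixes[:, 0].max() + pad - x0) / resolution))
    ny = int(np.ceil((fixes[:, 1].max() + pad - y0) / resolution))

    xc = x0 + (np.arange(nx) + 0.5) * resolution
    yc = y0 + (np.arange(ny) + 0.5) * resolution
    # separable kernel: density(y, x) = sum_i ky_i(y) kx_i(x)
    kx = np.exp(-0.5 * ((xc[:, None] - fixes[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((yc[:, None] - fixes[None, :, 1]) / h) ** 2)
    dens = ky @ kx.T
    masses = dens / dens.sum()
    return UtilizationDistribution(
        x0=float(x0),
        y0=float(y0),
        resolution=float(resolution),
        masses=masses,
        bandwidth=h,
        individual_id=individual_id,
    )


def _mask_to_polygon(mask: np.ndarray, x0: float, y0: float, res: float):
    """Union of the cell squares of a boolean grid mask (row-run merged)."""
    rects = []
    for j in range(mask.shape[0]):
        row = mask[j].astype(np.int8)
        d = np.diff(np.r_[0, row, 0])
        for s, e in zip(np.where(d == 1)[0], np.where(d == -1)[0]):
            rects.append((x0 + s * res, y0 + j * res, x0 + e * res, y0 + (j + 1) * res))
    r = np.asarray(rects)
    return unary_union(shapely.box(r[:, 0], r[:, 1], r[:, 2], r[:, 3]))


def isopleth(ud: UtilizationDistribution, level: float) -> RangePolygon:
    """Smallest cell set holding ``level`` percent of UD mass, polygonized.

    Cells are accumulated in order of decreasing density until the
    cumulative mass reaches ``level/100``; the enclosed mass therefore
    overshoots the level by at most one cell's mass.
    """
    if not (0 < level < 100):
        raise ValueError("level must be in (0, 100)")
    flat = ud.masses.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level / 100.0)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.masses.shape)

    poly = _mask_to_polygon(mask, ud.x0, ud.y0, ud.resolution)
    area = k * ud.resolution**2
    return RangePolygon(
        individual_id=ud.individual_id,
        level=float(level),
        polygon=poly,
        area_m2=float(area),
        enclosed_mass=float(cum[k - 1]),
    )


def total_distance(track: np.ndarray) -> float:
    """Summed Euclidean distance between consecutive retained fixes."""
    track = np.asarray(track, dtype=float)
    if len(track) < 2:
        warnings.warn("fewer than 2 fixes; total distance is 0")
        return 0.0
    return float(np.hypot(*np.diff(track, axis=0).T).sum())


def overlap_fraction(focal: RangePolygon, conspecifics: list) -> float:
    """Fraction of the focal range covered by conspecific ranges of the
    same isopleth level: area(focal intersect union(others)) / area(focal)."""
    if focal.polygon.area == 0:
        raise ValueError("zero-area focal polygon")
    for other in conspecifics:
        if other.level != focal.level:
            raise ValueError("overlap requires polygons at the same isopleth level")
    if not conspecifics:
        return 0.0
    union = unary_union([o.polygon for o in conspecifics])
    return float(focal.polygon.intersection(union).area / focal.polygon.area)


def mean_trapping_point(captures, trap_locations: np.ndarray | None = None):
    """Centroid of capture locations per individual (a home-center proxy).

    ``captures`` is the capture table with either x/y columns or a
    ``trap`` index column resolved against ``trap_locations``.  Repeated
    captures at one trap count as many times.
    """
    import pandas as pd

    df = captures.copy()
    if "x" not in df.columns or "y" not in df.columns:
        if trap_locations is None:
            raise ValueError("need trap_locations to resolve trap indices")
        df["x"] = trap_locations[df["trap"].to_numpy(int), 0]
        df["y"] = trap_locations[df["trap"].to_numpy(int), 1]
    if df.empty:
        warnings.warn("no captures: no mean trapping points")
        return pd.DataFrame(columns=["x", "y", "n_captures"])
    g = df.groupby("individual_id")
    out = g[["x", "y"]].mean()
    out["n_captures"] = g.size()
    return out


def count_points_in_range(
    points: np.ndarray, polygon: RangePolygon, exclude: np.ndarray | None = None
) -> int:
    """Count points inside or on the boundary of the range polygon.

    ``exclude`` marks points to skip (e.g. the focal individual's own
    trapping point).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        return 0
    keep = np.ones(len(points), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    geoms = [Point(p) for p in points[keep]]
    return int(sum(polygon.polygon.covers(g) for g in geoms))
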