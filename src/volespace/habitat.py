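"""Microhabitat rasters: inverse-distance-weighted interpolation of
per-trap vegetation measurements and extraction at telemetry fixes.

Cells follow the half-open convention: cell ``(i, j)`` covers
``[x0 + j*res, x0 + (j+1)*res) x [y0 + i*res, y0 + (i+1)*res)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HabitatRaster:
    x0: float
    y0: float
    resolution: float
    values: np.ndarray  # (ny, nx)
    layer: str = ""

    @property
    def extent(self) -> tuple:
        ny, nx = self.values.shape
        return (
            self.x0,
            self.y0,
            self.x0 + nx * self.resolution,
            self.y0 + ny * self.resolution,
        )


def idw_interpolate(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    x0: float,
    y0: float,
    nx: int,
    ny: int,
    resolution: float = 1.0,
    power: float = 2.0,
    layer: str = "",
) -> HabitatRaster:
    """Inverse-distance-weighted raster from point samples.

    Cell value = sum(w_i v_i) / sum(w_i) with w_i = d_i^(-power), using
    every sample (no search radius).  A cell whose center coincides with a
    sample takes the sample value exactly, and all outputs lie within the
    sample range.
    """
    xy = np.asarray(sample_xy, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 sample points")
    # conflicting duplicates are ill-posed for an exact interpolator
    uniq, inv = np.unique(xy.round(9), axis=0, return_inverse=True)
    if len(uniq) < len(xy):
        for g in range(len(uniq)):
            if np.ptp(v[inv == g]) > 0:
                raise ValueError("duplicate sample locations with conflicting values")

    xc = x0 + (np.arange(nx) + 0.5) * resolution
    yc = y0 + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xc, yc)
    d = np.hypot(gx[:, :, None] - xy[:, 0], gy[:, :, None] - xy[:, 1])
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d**-power
    w[exact] = 0.0
    num = (w * v).sum(axis=2)
    den = w.sum(axis=2)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    hit = exact.any(axis=2)
    if hit.any():
        out[hit] = v[np.argmax(exact, axis=2)[hit]]
    return HabitatRaster(
        x0=float(x0), y0=float(y0), resolution=float(resolution), values=out, layer=layer
    )


def raster_for_site(site, resolution: float = 1.0, power: float = 2.0, margin_m: float = 10.0):
    """Convenience: IDW rasters of both vegetation layers over the site."""
    veg = site.vegetation_samples
    xmin, ymin, xmax, ymax = site.extent
    x0, y0 = xmin - margin_m, ymin - margin_m
    nx = int(np.ceil((xmax + margin_m - x0) / resolution))
    ny = int(np.ceil((ymax + margin_m - y0) / resolution))
    xy = veg[["x", "y"]].to_numpy(float)
    return {
        layer: idw_interpolate(
            xy, veg[layer].to_numpy(float), x0, y0, nx, ny, resolution, power, layer
        )
        for layer in ("max_height_cm", "ground_cover_pct")
    }


def extract_at_fixes(raster: HabitatRaster, fixes: np.ndarray) -> np.ndarray:
    """Nearest-cell value at each fix under the half-open cell convention."""
    fixes = np.atleast_2d(np.asarray(fixes, dtype=float))
    jx = np.floor((fixes[:, 0] - raster.x0) / raster.resolution).astype(int)
    iy = np.floor((fixes[:, 1] - raster.y0) / raster.resolution).astype(int)
    ny, nx = raster.values.shape
    bad = (jx < 0) | (jx >= nx) | (iy < 0) | (iy >= ny)
    if bad.any():
        raise ValueError(
            f"{bad.sum()} fixes outside raster extent at rows {np.where(bad)[0].tolist()}"
        )
    return raster.values[iy, jx]


def range_means(
    fix_values: np.ndarray,
    fixes: np.ndarray,
    polygons: dict,
) -> dict:
    """Mean habitat value over the fixes inside each range polygon.

    ``polygons`` maps a label (e.g. level) to a RangePolygon; means are
    taken over member fixes, not raster cells, mirroring per-fix
    extraction followed by averaging.  A polygon containing no fixes gets
    ``nan``.
    """
    from shapely.geometry import Point

    fixes = np.atleast_2d(np.asarray(fixes, dtype=float))
    vals = np.asarray(fix_values, dtype=float)
    pts = [Point(p) for p in fixes]
    out = {}
    for label, rp in polygons.items():
        inside = np.array([rp.polygon.covers(p) for p in pts])
        if not inside.any():
            import warnings

            warnings.warn(f"no fixes inside polygon {label!r}; mean undefined")
            out[label] = float("nan")
        else:
            out[label] = float(vals[inside].mean())
    return out
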