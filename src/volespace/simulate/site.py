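"""Synthetic study site: trapping grid, antenna array and vegetation field.

A site is a fallow-land patch holding a 5 x 11 live-trapping grid with
~10 m trap spacing (55 traps, ~0.4 ha) surrounded by a rectangular array
of 8 omnidirectional antennas.  Vegetation is a two-regime mosaic: a
grass/herb matrix (lower maximum height, high ground cover) pierced by
shrub patches (taller maximum vegetation, low ground cover), measured in
a square meter around every trap.

Per-regime maximum vegetation heights are drawn from gamma distributions
moment-matched to the field means and SDs (grass 94.6 +/- 76.4 cm, shrub
151.9 +/- 105.6 cm); the gamma keeps heights non-negative while
preserving the stated mean, which a normal truncated at zero would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import child_rng
from ..geometry import AntennaGeometry

GRASS_HEIGHT_MEAN, GRASS_HEIGHT_SD = 94.6, 76.4
SHRUB_HEIGHT_MEAN, SHRUB_HEIGHT_SD = 151.9, 105.6
GRASS_COVER_MEAN, SHRUB_COVER_MEAN = 78.0, 38.0
COVER_SD = 12.0


@dataclass
class SiteConfig:
    rows: int = 5
    cols: int = 11
    spacing_m: float = 10.0
    n_shrub_patches: int = 3
    patch_radius_m: tuple = (8.0, 16.0)
    antenna_margin_m: float = 10.0

    def validate(self) -> None:
        if self.spacing_m <= 0:
            raise ValueError("trap spacing must be positive")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("trapping grid needs at least 2 rows and 2 columns")
        if self.n_shrub_patches < 0:
            raise ValueError("n_shrub_patches must be >= 0")


@dataclass
class SiteFixture:
    """One synthetic study site with known ground truth."""

    site_id: str
    trap_locations: np.ndarray          # (n_traps, 2) meters
    antenna_geometry: AntennaGeometry   # 8 antennas with side membership
    vegetation_samples: "object"        # DataFrame: trap, x, y, max_height_cm, ground_cover_pct
    extent: tuple                       # (xmin, ymin, xmax, ymax) of the trap grid
    shrub_patches: np.ndarray = field(default=None)  # (k, 3): x, y, radius

    def shrub_weight(self, xy: np.ndarray) -> np.ndarray:
        """Smooth 0-1 'shrubbiness' of locations (Gaussian patch kernels).

        Used by the population generator to express cover preference; the
        vegetation regime at each trap is the hard version of this field.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.shrub_patches is None or len(self.shrub_patches) == 0:
            return np.zeros(len(xy))
        cx, cy, r = (self.shrub_patches[:, i] for i in range(3))
        d2 = (xy[:, 0:1] - cx) ** 2 + (xy[:, 1:2] - cy) ** 2
        return np.exp(-0.5 * d2 / (r / 1.5) ** 2).max(axis=1)


def _gamma_params(mean: float, sd: float) -> tuple:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def make_site(config: SiteConfig | None = None, seed: int = 0, site_id: str = "S1") -> SiteFixture:
    """Generate a synthetic study site.

    Deterministic for a fixed ``(config, seed, site_id)``.
    """
    import pandas as pd

    config = config or SiteConfig()
    config.validate()
    rng = child_rng(seed, "site", site_id)

    xs = np.arange(config.cols) * config.spacing_m
    ys = np.arange(config.rows) * config.spacing_m
    gx, gy = np.meshgrid(xs, ys)
    traps = np.column_stack([gx.ravel(), gy.ravel()])
    extent = (0.0, 0.0, float(xs[-1]), float(ys[-1]))

    m = config.antenna_margin_m
    geometry = AntennaGeometry.from_rectangle(
        extent[0] - m, extent[1] - m, extent[2] + m, extent[3] + m
    )

    # shrub patches inside the grid extent
    k = config.n_shrub_patches
    r_lo, r_hi = config.patch_radius_m
    patches = np.column_stack(
        [
            rng.uniform(extent[0], extent[2], k),
            rng.uniform(extent[1], extent[3], k),
            rng.uniform(r_lo, r_hi, k),
        ]
    ) if k else np.empty((0, 3))

    # per-trap regime: shrub if the trap falls inside a patch circle
    in_shrub = np.zeros(len(traps), dtype=bool)
    for cx, cy, r in patches:
        in_shrub |= np.hypot(traps[:, 0] - cx, traps[:, 1] - cy) <= r

    heights = np.empty(len(traps))
    for mask, (mu, sd) in (
        (~in_shrub, (GRASS_HEIGHT_MEAN, GRASS_HEIGHT_SD)),
        (in_shrub, (SHRUB_HEIGHT_MEAN, SHRUB_HEIGHT_SD)),
    ):
        shape, scale = _gamma_params(mu, sd)
        heights[mask] = rng.gamma(shape, scale, mask.sum())

    cover_mean = np.where(in_shrub, SHRUB_COVER_MEAN, GRASS_COVER_MEAN)
    cover = np.clip(rng.normal(cover_mean, COVER_SD), 0.0, 100.0)

    veg = pd.DataFrame(
        {
            "trap": np.arange(len(traps)),
            "x": traps[:, 0],
            "y": traps[:, 1],
            "max_height_cm": heights,
            "ground_cover_pct": cover,
            "regime": np.where(in_shrub, "shrub", "grass"),
        }
    )
    return SiteFixture(
        site_id=site_id,
        trap_locations=traps,
        antenna_geometry=geometry,
        vegetation_samples=veg,
        extent=extent,
        shrub_patches=patches,
    )


def sample_grass_heights(n: int, seed: int = 0) -> np.ndarray:
    """Draws from the grass-regime maximum-height distribution (testing aid)."""
    shape, scale = _gamma_params(GRASS_HEIGHT_MEAN, GRASS_HEIGHT_SD)
    return child_rng(seed, "grass-heights").gamma(shape, scale, n)
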