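"""Synthetic vole population with latent behavioral types.

Each vole carries two standardized, mutually independent latent traits --
boldness and exploration -- that drive its space use through a
configurable effect structure:

* ``range_boldness`` / ``range_exploration``: slopes of log home-range
  scale (the stationary SD of the movement process, meters) on the traits.
* ``step_boldness`` / ``step_exploration``: slopes of log movement tempo
  (inverse of the home-range crossing time) on the traits.
* ``spacing_boldness``: slope of log target nearest-neighbour distance on
  boldness -- bolder voles settle farther from conspecifics, which is what
  produces their lower intraspecific overlap.
* ``shrub_pref_boldness``: slope of shrub-patch preference on boldness
  (negative by default: shy voles center their ranges under tall cover).

Home centers are placed sequentially: each vole scores a set of candidate
points by (a) how closely the nearest-neighbour distance to already-settled
voles matches its boldness-dependent target and (b) its cover preference,
and settles on the best candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import child_rng
from .site import SiteFixture


@dataclass
class EffectConfig:
    """Slopes of space-use parameters on the standardized latent traits."""

    range_boldness: float = 0.35
    range_exploration: float = 0.0
    step_boldness: float = 0.0
    step_exploration: float = 0.0
    spacing_boldness: float = 0.6
    shrub_pref_base: float = 2.2
    shrub_pref_boldness: float = -1.0
    range_resid_sd: float = 0.15  # lognormal residual on range scale

    @classmethod
    def null(cls) -> "EffectConfig":
        """All slopes and residual spread zero: every vole moves alike."""
        return cls(*([0.0] * 8))


@dataclass
class TrueVole:
    individual_id: str
    sex: str                  # 'F' or 'M'
    body_mass_g: float
    boldness_true: float
    exploration_true: float
    home_center: tuple
    range_scale_m: float      # stationary SD of the movement process
    tempo: float = 1.0        # multiplier on the mean-reversion rate
    site_id: str = "S1"


BASE_RANGE_SCALE_M = 12.0    # 95% range ~0.27 ha for the average vole
BASE_SPACING_M = 20.0
CANDIDATES = 64


def simulate_voles(
    site: SiteFixture,
    n: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> list:
    """Generate ``n`` voles with latent traits and settled home centers."""
    if n < 2:
        raise ValueError("need at least 2 voles")
    effects = effects if effects is not None else EffectConfig()
    rng = child_rng(seed, "voles", site.site_id)

    boldness = rng.standard_normal(n)
    exploration = rng.standard_normal(n)
    sex = np.array(["F", "M"])[(np.arange(n) + rng.integers(0, 2)) % 2]
    rng.shuffle(sex)
    mass = np.maximum(rng.normal(24.0, 3.5, n), 17.5)  # adults only (>17 g)

    log_range = (
        np.log(BASE_RANGE_SCALE_M)
        + effects.range_boldness * boldness
        + effects.range_exploration * exploration
        + effects.range_resid_sd * rng.standard_normal(n)
    )
    range_scale = np.exp(log_range)
    tempo = np.exp(
        effects.step_boldness * boldness + effects.step_exploration * exploration
    )

    xmin, ymin, xmax, ymax = site.extent
    target_nn = BASE_SPACING_M * np.exp(effects.spacing_boldness * boldness)
    shrub_pref = effects.shrub_pref_base + effects.shrub_pref_boldness * boldness

    # settle voles one at a time, boldest first (bold voles claim isolated spots)
    order = np.argsort(-boldness)
    centers = np.full((n, 2), np.nan)
    placed: list = []
    for i in order:
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, CANDIDATES), rng.uniform(ymin, ymax, CANDIDATES)]
        )
        score = shrub_pref[i] * site.shrub_weight(cand)
        if placed:
            d = np.hypot(
                cand[:, 0:1] - np.array(placed)[:, 0],
                cand[:, 1:2] - np.array(placed)[:, 1],
            ).min(axis=1)
            score = score - np.abs(d - target_nn[i]) / BASE_SPACING_M
        best = int(np.argmax(score))
        centers[i] = cand[best]
        placed.append(cand[best])

    return [
        TrueVole(
            individual_id=f"{site.site_id}-V{i + 1:02d}",
            sex=str(sex[i]),
            body_mass_g=float(mass[i]),
            boldness_true=float(boldness[i]),
            exploration_true=float(exploration[i]),
            home_center=(float(centers[i, 0]), float(centers[i, 1])),
            range_scale_m=float(range_scale[i]),
            tempo=float(tempo[i]),
            site_id=site.site_id,
        )
        for i in range(n)
    ]
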