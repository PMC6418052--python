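"""Movement simulation: discrete-time Ornstein-Uhlenbeck home-range process.

The OU process is the simplest stationary model of a central-place
forager: positions revert to the home center with characteristic time
``tau_home`` and have an isotropic bivariate-normal stationary
distribution whose SD is the vole's ``range_scale_m``.  Sampled at the
tracking cadence (20 min) over 4 days this yields 288 true positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import child_rng
from .population import TrueVole

TAU_HOME_MIN = 60.0  # home-range crossing time for an average-tempo vole


@dataclass
class Trajectory:
    individual_id: str
    times_min: np.ndarray   # strictly increasing, minutes from tracking start
    xy: np.ndarray          # (n, 2) true positions, meters


def simulate_movement(
    vole: TrueVole,
    days: float = 4.0,
    cadence_min: float = 20.0,
    seed: int = 0,
    tau_home_min: float = TAU_HOME_MIN,
) -> Trajectory:
    """Simulate one vole's true track.

    The process starts at stationarity, so every fix is a draw from the
    stationary law N(home_center, range_scale**2 * I); consecutive fixes
    are correlated with coefficient exp(-cadence / tau).
    """
    if days <= 0 or cadence_min <= 0:
        raise ValueError("days and cadence_min must be positive")
    rng = child_rng(seed, "movement", vole.individual_id)

    n = int(round(days * 24 * 60 / cadence_min))
    tau = tau_home_min / max(vole.tempo, 1e-9)
    phi = np.exp(-cadence_min / tau)
    s = vole.range_scale_m
    step_sd = s * np.sqrt(1.0 - phi**2)

    eps = rng.standard_normal((n, 2))
    dev = np.empty((n, 2))
    dev[0] = s * eps[0]
    for t in range(1, n):
        dev[t] = phi * dev[t - 1] + step_sd * eps[t]

    xy = dev + np.array(vole.home_center)
    times = np.arange(n) * cadence_min
    return Trajectory(individual_id=vole.individual_id, times_min=times, xy=xy)
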