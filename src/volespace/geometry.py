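"""Antenna-array geometry for signal-strength localization.

The receiving array is a rectangle of eight omnidirectional antennas
surrounding the trapping grid: one antenna on each corner and one at the
midpoint of each side.  Each side of the rectangle therefore has three
member antennas (its two corners plus its midpoint), with corner antennas
shared by the two adjacent sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIDES = ("N", "E", "S", "W")

# opposing pairs used for the coordinate proportions: x grows W -> E,
# y grows S -> N
OPPOSING = {"x": ("E", "W"), "y": ("N", "S")}


@dataclass(frozen=True)
class AntennaGeometry:
    """Positions of the 8 antennas and their side membership.

    Parameters
    ----------
    antennas
        ``(8, 2)`` array of x-y positions in meters.
    sides
        Mapping side name -> tuple of exactly 3 antenna indices.
    """

    antennas: np.ndarray
    sides: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.antennas, dtype=float)
        if a.shape != (8, 2):
            raise ValueError(f"expected 8 antenna positions, got shape {a.shape}")
        object.__setattr__(self, "antennas", a)
        for s in SIDES:
            if s not in self.sides:
                raise ValueError(f"side {s!r} missing from geometry")
            if len(self.sides[s]) != 3:
                raise ValueError(
                    f"side {s!r} has {len(self.sides[s])} antennas, expected 3"
                )

    @classmethod
    def from_rectangle(
        cls, xmin: float, ymin: float, xmax: float, ymax: float
    ) -> "AntennaGeometry":
        """Standard array: corners SW, SE, NE, NW (0-3), side midpoints
        S, E, N, W (4-7)."""
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate rectangle")
        xm, ym = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
        antennas = np.array(
            [
                (xmin, ymin),  # 0 SW
                (xmax, ymin),  # 1 SE
                (xmax, ymax),  # 2 NE
                (xmin, ymax),  # 3 NW
                (xm, ymin),    # 4 S mid
                (xmax, ym),    # 5 E mid
                (xm, ymax),    # 6 N mid
                (xmin, ym),    # 7 W mid
            ]
        )
        sides = {
            "S": (0, 4, 1),
            "E": (1, 5, 2),
            "N": (2, 6, 3),
            "W": (3, 7, 0),
        }
        return cls(antennas=antennas, sides=sides)

    def translated(self, dx: float, dy: float) -> "AntennaGeometry":
        return AntennaGeometry(
            antennas=self.antennas + np.array([dx, dy]), sides=dict(self.sides)
        )

    @property
    def center(self) -> np.ndarray:
        return self.antennas.mean(axis=0)
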