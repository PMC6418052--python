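"""Signal-strength localization for an automated radio-telemetry array.

The receiving units record each transmitter seven times in a row at every
antenna.  The chain to an x-y fix is:

1. per-antenna median of the 7 repeats (robust to single disturbed pulses);
2. side sums over the four sides of the rectangular array (3 antennas per
   side, corners shared by adjacent sides), on background-subtracted,
   floor-clamped medians;
3. opposing-side proportions, ``p_x = E / (E + W)`` and
   ``p_y = N / (N + S)``;
4. a calibrated monotone (isotonic, piecewise-linear) map from each
   proportion to a coordinate, fitted on known-location test-transmitter
   scans;
5. removal of obvious outliers: fixes farther than 50 m from both of
   their temporal neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .geometry import OPPOSING, SIDES, AntennaGeometry

N_REPEATS = 7
SIDE_FLOOR = 1e-9
OUTLIER_THRESHOLD_M = 50.0


class NoSignalError(ValueError):
    """Raised when a scan carries no signal above background on any side."""


def aggregate_scan(scan: np.ndarray) -> np.ndarray:
    """Median strength per antenna for one scan of shape ``(8, 7)``."""
    scan = np.asarray(scan, dtype=float)
    if scan.ndim != 2 or scan.shape[1] != N_REPEATS:
        raise ValueError(
            f"scan must have {N_REPEATS} repeats per antenna, got shape {scan.shape}"
        )
    return np.median(scan, axis=1)


def side_sums(medians: np.ndarray, geometry: AntennaGeometry) -> dict:
    """Sum the per-antenna medians over each side (N, E, S, W).

    Corner antennas are members of both adjacent sides and contribute to
    both sums.
    """
    medians = np.asarray(medians, dtype=float)
    if medians.shape[-1] != 8:
        raise ValueError("expected 8 per-antenna medians")
    return {s: float(medians[..., list(geometry.sides[s])].sum(-1)) for s in SIDES}


def _side_matrix(geometry: AntennaGeometry) -> np.ndarray:
    """(4, 8) membership matrix in SIDES order, for vectorized use."""
    m = np.zeros((4, 8))
    for i, s in enumerate(SIDES):
        m[i, list(geometry.sides[s])] = 1.0
    return m


def _proportions(
    medians: np.ndarray, geometry: AntennaGeometry, background: float
) -> np.ndarray:
    """Opposing-side proportions (p_x, p_y) for medians of shape (..., 8)."""
    clamped = np.maximum(np.asarray(medians, float) - background, SIDE_FLOOR)
    sums = clamped @ _side_matrix(geometry).T  # (..., 4) in N,E,S,W order
    n, e, s, w = (sums[..., i] for i in range(4))
    return np.stack([e / (e + w), n / (n + s)], axis=-1)


@dataclass
class CalibrationModel:
    """Monotone proportion -> coordinate maps for both axes.

    ``x_knots``/``y_knots`` are ``(proportion, coordinate)`` pairs from an
    isotonic fit; prediction is linear interpolation between them, clamped
    to the end values outside the calibrated proportion span.
    """

    x_knots: np.ndarray
    y_knots: np.ndarray
    background_db: float
    n_points: int
    residual_rms_m: float
    meta: dict = field(default_factory=dict)

    def predict(self, proportions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(proportions)
        x = np.interp(p[:, 0], self.x_knots[:, 0], self.x_knots[:, 1])
        y = np.interp(p[:, 1], self.y_knots[:, 0], self.y_knots[:, 1])
        return np.column_stack([x, y])


def _fit_axis(props: np.ndarray, coords: np.ndarray) -> np.ndarray:
    if np.ptp(coords) == 0:
        raise ValueError("calibration points do not span the axis")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(props, coords)
    order = np.argsort(props)
    knots = np.column_stack([props[order], fitted[order]])
    # collapse duplicate proportions (isotonic fit gives them one value)
    _, keep = np.unique(knots[:, 0], return_index=True)
    return knots[keep]


def fit_calibration(
    known_points: np.ndarray,
    scans: np.ndarray,
    geometry: AntennaGeometry,
    background_db: float | None = None,
) -> CalibrationModel:
    """Fit the proportion -> coordinate maps from known-location scans.

    Parameters
    ----------
    known_points
        ``(k, 2)`` true transmitter positions, k >= 3 spanning both axes.
    scans
        ``(k, 8, 7)`` raw strengths.
    background_db
        Receiver background level subtracted per antenna before summing.
        Defaults to just below the weakest median seen during calibration.
    """
    known_points = np.asarray(known_points, dtype=float)
    scans = np.asarray(scans, dtype=float)
    if len(known_points) < 3:
        raise ValueError("need at least 3 calibration points")
    if scans.shape[0] != len(known_points):
        raise ValueError("one scan per known point required")

    medians = np.median(scans, axis=2)
    if background_db is None:
        background_db = float(medians.min()) - 1.0

    props = _proportions(medians, geometry, background_db)
    x_knots = _fit_axis(props[:, 0], known_points[:, 0])
    y_knots = _fit_axis(props[:, 1], known_points[:, 1])

    model = CalibrationModel(
        x_knots=x_knots,
        y_knots=y_knots,
        background_db=background_db,
        n_points=len(known_points),
        residual_rms_m=0.0,
    )
    pred = model.predict(props)
    model.residual_rms_m = float(
        np.sqrt(np.mean(np.sum((pred - known_points) ** 2, axis=1)))
    )
    return model


def localize(
    scan: np.ndarray, calibration: CalibrationModel, geometry: AntennaGeometry
) -> tuple:
    """Localize one ``(8, 7)`` scan; returns ``(x, y)`` in meters."""
    medians = aggregate_scan(scan)
    if np.all(medians <= calibration.background_db):
        raise NoSignalError("no signal above background on any antenna")
    props = _proportions(medians, geometry, calibration.background_db)
    xy = calibration.predict(props)[0]
    return float(xy[0]), float(xy[1])


def localize_scans(
    scans: pd.DataFrame,
    calibration: CalibrationModel,
    geometry: AntennaGeometry,
) -> pd.DataFrame:
    """Localize a long-format scan table into a fix table.

    ``scans`` needs columns ``timestamp_min, individual_id, antenna,
    repeat_1..repeat_7`` (8 rows per scan).  Scans with no signal above
    background are dropped with a warning.
    """
    rep_cols = [f"repeat_{r + 1}" for r in range(N_REPEATS)]
    wide = scans.sort_values(["individual_id", "timestamp_min", "antenna"])
    groups = wide.groupby(["individual_id", "timestamp_min"], sort=True)
    arr = wide[rep_cols].to_numpy(float).reshape(groups.ngroups, 8, N_REPEATS)
    keys = np.array(list(groups.groups.keys()), dtype=object)

    medians = np.median(arr, axis=2)
    ok = ~np.all(medians <= calibration.background_db, axis=1)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} scans carried no signal and were dropped")
    props = _proportions(medians[ok], geometry, calibration.background_db)
    xy = calibration.predict(props)
    return pd.DataFrame(
        {
            "individual_id": [k[0] for k in keys[ok]],
            "timestamp_min": [float(k[1]) for k in keys[ok]],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    ).sort_values(["individual_id", "timestamp_min"], ignore_index=True)


def filter_outliers(
    track: pd.DataFrame, threshold_m: float = OUTLIER_THRESHOLD_M
) -> pd.DataFrame:
    """Flag localization outliers on a time-ordered single-individual track.

    A fix is flagged ``removed_outlier`` when its distance to *both*
    temporal neighbors (its only neighbor, at the track ends) exceeds the
    threshold -- isolated jumps blamed on disturbance such as strong wind.
    Distances are measured on the original track in a single pass, so the
    rule is idempotent on its own output.
    """
    track = track.reset_index(drop=True)
    n = len(track)
    out = track.copy()
    if n < 3:
        warnings.warn("track has fewer than 3 fixes; outlier filter skipped")
        out["qc_flag"] = "ok"
        return out

    xy = track[["x", "y"]].to_numpy(float)
    d = np.hypot(*(np.diff(xy, axis=0).T))  # d[i] = dist(i, i+1)
    far_prev = np.r_[np.inf, d] > threshold_m   # endpoint has no previous
    far_next = np.r_[d, np.inf] > threshold_m
    removed = far_prev & far_next
    out["qc_flag"] = np.where(removed, "removed_outlier", "ok")
    return out
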