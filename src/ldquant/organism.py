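"""Whole-organism readouts: calibration curves, swim tracks, pooling.

Covers the organism-level quantifications around peptide feeding studies:

* a fluorescence-vs-concentration calibration line and its inverse
  (estimating peptide concentration in lysate from measured fluorescence,
  with the classical inverse-prediction standard error);
* locomotion metrics from time-stamped larval tracks -- total distance
  travelled and mean absolute angular speed during motion;
* the first-stop zone after a startle stimulus, on a user-supplied
  concentric zone scheme;
* pooling-design bookkeeping (animals per replicate x replicates x
  conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "Track",
    "ZoneScheme",
    "PoolingDesign",
    "TrackMetrics",
    "FirstStop",
    "fit_calibration",
    "estimate_concentration",
    "track_metrics",
    "first_stop_zone",
    "pooling_totals",
]


@dataclass
class CalibrationCurve:
    slope: float  # a.u. per (ug/mL)
    intercept: float  # a.u.
    r_squared: float
    n_points: int
    residual_sd: float  # a.u.
    mean_y: float
    sxx: float  # sum of squared concentration deviations


@dataclass
class Track:
    larva_id: int
    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("track coordinates must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, larva_id: int) -> "Track":
        sub = df[df["larva_id"] == larva_id].sort_values("t")
        return cls(larva_id=larva_id, t=sub["t"].to_numpy(),
                   x=sub["x"].to_numpy(), y=sub["y"].to_numpy())


@dataclass
class ZoneScheme:
    center: tuple[float, float]
    ring_radii: tuple[float, ...]  # strictly increasing, px

    def __post_init__(self):
        radii = np.asarray(self.ring_radii, dtype=float)
        if radii.size == 0 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ValueError("ring_radii must be positive and strictly increasing")

    def zone_of(self, x: float, y: float) -> tuple[int, bool]:
        """1-based zone index from the centre outward; flag when outside all."""
        r = float(np.hypot(x - self.center[0], y - self.center[1]))
        radii = np.asarray(self.ring_radii)
        idx = int(np.searchsorted(radii, r, side="left")) + 1
        if idx > len(radii):
            return len(radii), True
        return idx, False


@dataclass
class PoolingDesign:
    n_per_replicate: int
    n_replicates: int
    n_conditions: int

    @property
    def total(self) -> int:
        return self.n_per_replicate * self.n_replicates * self.n_conditions


@dataclass
class TrackMetrics:
    larva_id: int
    total_distance: float  # px
    mean_angular_speed: float  # rad/s; 0 (flagged) when undefined
    angular_speed_defined: bool
    n_samples: int


@dataclass
class FirstStop:
    larva_id: int
    stopped: bool
    t_stop: float | None
    zone: int | None
    outside_zones: bool = False


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, fluorescence).

    Unweighted, matching serial-dilution practice where replicate variances
    are not recorded.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, fluorescence) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all concentrations are equal; line is undetermined")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    dof = max(len(x) - 2, 1)
    resid_sd = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
        residual_sd=resid_sd,
        mean_y=float(y.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def estimate_concentration(
    curve: CalibrationCurve, fluorescence: float, n_replicates: int = 1
) -> tuple[float, float, bool]:
    """Invert the calibration line: (estimate ug/mL, SE, floored_flag).

    Negative estimates are floored at zero and flagged. The standard error
    is the classical inverse-prediction formula.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; curve not invertible")
    est = (fluorescence - curve.intercept) / curve.slope
    se = (curve.residual_sd / abs(curve.slope)) * np.sqrt(
        1.0 / n_replicates
        + 1.0 / curve.n_points
        + (fluorescence - curve.mean_y) ** 2 / (curve.slope**2 * curve.sxx)
    )
    floored = est < 0
    if floored:
        est = 0.0
    return float(est), float(se), bool(floored)


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------


def track_metrics(track: Track, jitter_floor: float = 0.5) -> TrackMetrics:
    """Total path length and mean absolute heading-change rate.

    Headings come from atan2 of the step vector; the angular speed at an
    interior sample is the wrapped heading change divided by the elapsed
    time, averaged over interior samples whose adjacent steps both exceed
    ``jitter_floor`` px (so positional noise at rest does not masquerade as
    turning). Stationary tracks have no defined heading and return a flagged
    zero.
    """
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    steps = np.hypot(dx, dy)
    total = float(steps.sum())

    if track.t.size < 3:
        if total == 0.0:
            warnings.warn("stationary track: angular speed undefined", stacklevel=2)
        return TrackMetrics(track.larva_id, total, 0.0, False, track.t.size)

    headings = np.arctan2(dy, dx)
    dtheta = np.diff(headings)
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    dt_mid = track.t[2:] - track.t[1:-1]
    moving = (steps[:-1] > jitter_floor) & (steps[1:] > jitter_floor)
    if not moving.any():
        warnings.warn(
            f"track {track.larva_id}: no motion above the jitter floor; "
            "angular speed set to 0 (flagged)",
            stacklevel=2,
        )
        return TrackMetrics(track.larva_id, total, 0.0, False, track.t.size)
    omega = np.abs(dtheta[moving]) / dt_mid[moving]
    return TrackMetrics(track.larva_id, total, float(omega.mean()), True,
                        track.t.size)


def first_stop_zone(
    track: Track,
    zones: ZoneScheme,
    speed_threshold: float = 1.0,
    dwell: float = 0.5,
) -> FirstStop:
    """Zone containing the larva when it first stays slow for >= ``dwell`` s.

    Speed is evaluated per step; the stop time is the start of the first run
    of consecutive sub-threshold steps spanning at least ``dwell`` seconds.
    A track that never satisfies the criterion returns ``stopped=False``
    (the "no-stop" sentinel).
    """
    dt = np.diff(track.t)
    speed = np.hypot(np.diff(track.x), np.diff(track.y)) / dt
    slow = speed < speed_threshold
    i = 0
    n = len(slow)
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            span = track.t[j] - track.t[i]
            if span >= dwell:
                t_stop = float(track.t[i])
                zone, outside = zones.zone_of(track.x[i], track.y[i])
                if outside:
                    warnings.warn(
                        f"track {track.larva_id}: stop position outside the "
                        "outermost zone; assigned to it (flagged)",
                        stacklevel=2,
                    )
                return FirstStop(track.larva_id, True, t_stop, zone, outside)
            i = j
        else:
            i += 1
    return FirstStop(track.larva_id, False, None, None)


# ---------------------------------------------------------------------------
# pooling bookkeeping
# ---------------------------------------------------------------------------


def pooling_totals(design: PoolingDesign) -> pd.DataFrame:
    """Per-condition and grand totals of pooled animals (heads == tails).

    The grand total is n_per_replicate x n_replicates x n_conditions, e.g.
    30 x 3 x 3 = 270 heads and 270 tails.
    """
    if min(design.n_per_replicate, design.n_replicates, design.n_conditions) <= 0:
        raise ValueError("all pooling counts must be positive")
    per_condition = design.n_per_replicate * design.n_replicates
    rows = [
        dict(condition=k + 1, heads=per_condition, tails=per_condition)
        for k in range(design.n_conditions)
    ]
    out = pd.DataFrame(rows)
    out.attrs["total_heads"] = design.total
    out.attrs["total_tails"] = design.total
    return out
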