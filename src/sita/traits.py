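"""Geometric root traits from traced polylines.

All angles follow the image convention used by flatbed-scanner and
time-lapse root phenotyping: ``x`` increases rightward, ``y`` increases
*downward*, so the gravity vector is ``(0, +1)``.  A signed angle of 0
means a root segment pointing straight down; positive angles open toward
``+x`` (rightward), negative toward ``-x``.  Angles are reported in
degrees in the half-open interval ``(-180, 180]``.

The two headline traits are

* **RTD** (root tip direction): the signed angle of the chord spanning
  the last fraction (default 10%) of the traced root's arc length.
* **RVA** (root vector angle): the signed angle of the straight vector
  from the root's position at transfer (first point of the first frame)
  to the current tip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RootPolyline",
    "RootTimeSeries",
    "AngleMeasure",
    "arc_length",
    "point_at_fraction",
    "rtd_angle",
    "rva_angle",
    "growth_rate",
    "trait_timeseries",
    "halotropism_angle",
    "fold_angle_deg",
    "signed_angle_deg",
]

TRAIT_COLUMNS = [
    "plant_id",
    "treatment",
    "time_h",
    "rtd_deg",
    "rva_deg",
    "length_cm",
    "growth_rate_cm_per_h",
]


def fold_angle_deg(deg: float) -> float:
    """Fold an angle in degrees into (-180, 180]."""
    folded = (deg + 180.0) % 360.0 - 180.0
    if folded == -180.0:
        folded = 180.0
    return folded


def signed_angle_deg(dx: float, dy: float) -> float:
    """Signed angle between gravity (+y, image convention) and (dx, dy).

    Computed as the two-argument arctangent ``atan2(dx, dy)`` so that a
    vector pointing straight down (dy > 0) maps to 0 deg and a vector
    pointing right (+x) maps to +90 deg.
    """
    return math.degrees(math.atan2(dx, dy))


@dataclass(frozen=True)
class AngleMeasure:
    """A signed angle in degrees, or an explicit 'undefined' flag.

    ``value_deg`` is NaN when ``defined`` is False; ``reason`` then holds
    a short machine-readable code (e.g. ``"degenerate_tip"``).
    """

    value_deg: float
    defined: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.defined and not math.isfinite(self.value_deg):
            raise ValueError("defined angle must be finite")
        if self.defined and not (-180.0 < self.value_deg <= 180.0):
            raise ValueError(f"angle {self.value_deg} outside (-180, 180]")


@dataclass
class RootPolyline:
    """Ordered 2-D trace of one root at one time point (cm, image coords)."""

    points: np.ndarray  # (n, 2) float array
    plant_id: str = "plant"
    time_h: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline coordinates must be finite")
        # drop exact duplicate consecutive points (tracing artifacts)
        if len(pts) >= 2:
            keep = np.ones(len(pts), dtype=bool)
            same = np.all(pts[1:] == pts[:-1], axis=1)
            if same.any():
                logger.warning(
                    "dropping %d duplicate consecutive point(s) in plant %s @ %.2f h",
                    int(same.sum()), self.plant_id, self.time_h,
                )
                keep[1:] = ~same
            pts = pts[keep]
        if len(pts) < 2:
            raise ValueError("polyline needs at least 2 distinct points")
        self.points = pts

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    @property
    def base(self) -> np.ndarray:
        return self.points[0]


@dataclass
class RootTimeSeries:
    """Per-plant sequence of polylines on a regular time grid."""

    polylines: list[RootPolyline]
    treatment: str = "control"
    headings_deg: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.polylines:
            raise ValueError("empty time series")
        times = self.times_h
        if np.any(np.diff(times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def times_h(self) -> np.ndarray:
        return np.array([p.time_h for p in self.polylines])

    @property
    def plant_id(self) -> str:
        return self.polylines[0].plant_id

    def frame_at(self, time_h: float, tol_h: float | None = None) -> RootPolyline:
        """Nearest frame to ``time_h`` within ``tol_h`` (default dt/2).

        Raises ``KeyError`` when no frame is close enough — no silent
        extrapolation.
        """
        times = self.times_h
        if tol_h is None:
            dt = np.min(np.diff(times)) if len(times) > 1 else np.inf
            tol_h = dt / 2.0
        i = int(np.argmin(np.abs(times - time_h)))
        if abs(times[i] - time_h) > tol_h + 1e-12:
            raise KeyError(
                f"no frame within {tol_h:g} h of t={time_h:g} h "
                f"(nearest: {times[i]:g} h)"
            )
        return self.polylines[i]


def arc_length(polyline: RootPolyline) -> float:
    """Total arc length of the trace in cm (sum of segment lengths)."""
    seg = np.diff(polyline.points, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def point_at_fraction(polyline: RootPolyline, f: float) -> np.ndarray:
    """Point at arc-length fraction ``f`` in [0, 1] along the trace.

    Linearly interpolated within the containing segment; ``f=0`` returns
    the base point and ``f=1`` the tip.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction {f} outside [0, 1]")
    pts = polyline.points
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    target = f * cum[-1]
    i = int(np.searchsorted(cum, target, side="right")) - 1
    i = min(i, len(seglen) - 1)
    remain = target - cum[i]
    frac = remain / seglen[i]
    return pts[i] + frac * seg[i]


def rtd_angle(polyline: RootPolyline, tip_fraction: float = 0.10) -> AngleMeasure:
    """Root tip direction: signed angle of the chord over the last
    ``tip_fraction`` of arc length (default, the last 10%)."""
    if not (0.0 < tip_fraction <= 1.0):
        raise ValueError("tip_fraction must be in (0, 1]")
    start = point_at_fraction(polyline, 1.0 - tip_fraction)
    d = polyline.tip - start
    if np.hypot(d[0], d[1]) < 1e-12:
        return AngleMeasure(math.nan, defined=False, reason="degenerate_tip")
    return AngleMeasure(fold_angle_deg(signed_angle_deg(d[0], d[1])))


def rva_angle(series: RootTimeSeries, time_h: float,
              tol_h: float | None = None) -> AngleMeasure:
    """Root vector angle: signed angle of the base-to-tip vector.

    The base is the first point of the *first* frame (root position at
    transfer); the tip is taken from the frame nearest ``time_h``.
    """
    frame = series.frame_at(time_h, tol_h)
    base = series.polylines[0].base
    d = frame.tip - base
    if np.hypot(d[0], d[1]) < 1e-12:
        return AngleMeasure(math.nan, defined=False, reason="zero_base_to_tip")
    return AngleMeasure(fold_angle_deg(signed_angle_deg(d[0], d[1])))


def growth_rate(series: RootTimeSeries,
                shrink_tol_cm: float = 1e-9) -> np.ndarray:
    """Per-interval growth rate in cm/h; length = n_frames - 1.

    Traces shrinking between frames beyond ``shrink_tol_cm`` indicate a
    tracing error and are rejected.
    """
    if len(series.polylines) < 2:
        raise ValueError("need at least 2 frames for a growth rate")
    lengths = np.array([arc_length(p) for p in series.polylines])
    times = series.times_h
    dL = np.diff(lengths)
    if np.any(dL < -shrink_tol_cm):
        raise ValueError("root length decreases between frames beyond tolerance")
    return dL / np.diff(times)


def trait_timeseries(series: RootTimeSeries,
                     tip_fraction: float = 0.10) -> pd.DataFrame:
    """Per-frame trait table: RTD, RVA, length, growth rate.

    One row per frame.  Undefined angles are carried as NaN with a reason
    code in ``rtd_reason`` / ``rva_reason``; the growth rate of frame 0
    is NaN (no preceding interval).
    """
    rows = []
    rates = growth_rate(series) if len(series.polylines) >= 2 else np.array([])
    for i, poly in enumerate(series.polylines):
        rtd = rtd_angle(poly, tip_fraction)
        rva = rva_angle(series, poly.time_h)
        rows.append({
            "plant_id": poly.plant_id,
            "treatment": series.treatment,
            "time_h": poly.time_h,
            "rtd_deg": rtd.value_deg,
            "rva_deg": rva.value_deg,
            "length_cm": arc_length(poly),
            "growth_rate_cm_per_h": rates[i - 1] if i > 0 else math.nan,
            "rtd_reason": rtd.reason,
            "rva_reason": rva.reason,
        })
    return pd.DataFrame(rows)


def halotropism_angle(series: RootTimeSeries, t0_h: float, t_h: float,
                      tip_fraction: float = 0.10) -> float:
    """Tip re-orientation between two times: RTD(t) - RTD(t0), degrees.

    Quantifies the directional (salt-avoidance) response since gradient
    application; implemented as the change in tip heading rather than the
    absolute angle.
    """
    a0 = rtd_angle(series.frame_at(t0_h), tip_fraction)
    a1 = rtd_angle(series.frame_at(t_h), tip_fraction)
    if not (a0.defined and a1.defined):
        raise ValueError("undefined tip direction at one of the requested times")
    return a1.value_deg - a0.value_deg
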