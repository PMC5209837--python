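"""Growth-curve quantification for camera-based plate growth monitors.

A Growth Profiler style instrument reports culture density as a green-channel
intensity ("G-value") per well per scan.  G-values are converted to OD600
equivalents with a power-law calibration, and the maximum specific growth
rate (µ_max, h⁻¹) is estimated as the steepest slope of ln(OD) over a
sliding window of consecutive samples.  The lag phase is the classical
geometric construction: the intersection of the maximum-growth tangent with
the initial-density baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class CalibrationModel:
    """Power-law G-value → OD600 calibration: OD = a · G^b."""

    a: float = 0.000000061761
    b: float = 3.4784

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("calibration coefficients must be positive")


#: Instrument calibration used throughout: OD600 equivalent = 6.1761e-8 * G^3.4784.
DEFAULT_CALIBRATION = CalibrationModel()


def g_to_od(g, cal: CalibrationModel = DEFAULT_CALIBRATION):
    """Convert G-value(s) to OD600 equivalents, OD = a · G^b.

    Raises ValueError for non-positive G-values.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("G-values must be positive")
    out = cal.a * g**cal.b
    return float(out) if out.ndim == 0 else out


def od_to_g(od, cal: CalibrationModel = DEFAULT_CALIBRATION):
    """Inverse calibration: G = (OD / a)^(1/b)."""
    od = np.asarray(od, dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    out = (od / cal.a) ** (1.0 / cal.b)
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthCurve:
    """One well's time series, either raw G-values or OD equivalents.

    times are hours and strictly increasing; values are positive.
    """

    times: np.ndarray
    values: np.ndarray
    value_kind: str = "OD"  # "G" or "OD"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) < 4:
            raise ValueError("need at least 4 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("values must be positive")
        if self.value_kind not in ("G", "OD"):
            raise ValueError("value_kind must be 'G' or 'OD'")

    def to_od(self, cal: CalibrationModel = DEFAULT_CALIBRATION) -> "GrowthCurve":
        if self.value_kind == "OD":
            return self
        return GrowthCurve(self.times, g_to_od(self.values, cal), "OD")


@dataclass
class GrowthStats:
    mu_max: float  # h^-1, >= 0
    lag: Optional[float]  # h; None when mu_max == 0
    window: tuple[float, float] = (0.0, 0.0)  # start/end hours of fitted stretch
    r_squared: float = field(default=0.0)
    intercept: float = 0.0  # ln(OD) intercept of the fitted line


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median, edges passed through."""
    out = x.copy()
    if len(x) >= 3:
        stacked = np.stack([x[:-2], x[1:-1], x[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def estimate_mu_max(
    curve: GrowthCurve,
    window_points: int = 7,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    median_filter: bool = False,
) -> GrowthStats:
    """µ_max as the steepest least-squares slope of ln(OD) over sliding windows.

    The default window of 7 points spans ≈4.7 h at a 40-min scan interval;
    noisier curves warrant a longer window (see package docs).  Negative best
    slopes (declining or flat noisy curves) are reported as µ_max = 0.
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    curve = curve.to_od(cal)
    n = len(curve.times)
    if n < window_points:
        raise ValueError(f"curve has {n} points, need >= {window_points}")
    t = curve.times
    od = _median3(curve.values) if median_filter else curve.values
    y = np.log(od)

    best = (-np.inf, 0)  # (slope, start index)
    for i in range(n - window_points + 1):
        tw = t[i : i + window_points]
        yw = y[i : i + window_points]
        slope = np.polyfit(tw, yw, 1)[0]
        if slope > best[0]:
            best = (slope, i)
    slope, i = best
    tw = t[i : i + window_points]
    yw = y[i : i + window_points]
    coef = np.polyfit(tw, yw, 1)
    resid = yw - np.polyval(coef, tw)
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    mu = max(0.0, float(coef[0]))
    if mu < 1e-12:  # numerically flat
        mu = 0.0
    stats = GrowthStats(
        mu_max=mu,
        lag=None,
        window=(float(tw[0]), float(tw[-1])),
        r_squared=min(1.0, max(0.0, r2)),
        intercept=float(coef[1]),
    )
    if mu > 0:
        stats.lag = estimate_lag(curve, stats)
    return stats


def estimate_lag(curve: GrowthCurve, stats: GrowthStats) -> Optional[float]:
    """Geometric lag: where the max-growth tangent meets the initial baseline.

    The fitted line ln(OD) = µ·t + c intersects ln(OD_initial) at
    t = (ln OD_initial − c)/µ, clipped to [0, window start].  The initial
    density is the first scan (the known inoculation density).  Undefined
    (None) when µ_max is zero.
    """
    if stats.mu_max <= 0:
        return None
    curve = curve.to_od()
    base = float(np.log(curve.values[0]))
    lag = (base - stats.intercept) / stats.mu_max
    return float(np.clip(lag, 0.0, stats.window[0]))


def cells_from_od(od: float, od_ref: float = 0.2, cells_ref: float = 4.0e6) -> float:
    """Cell density from OD600, linear through the origin.

    Default anchor: OD 0.2 corresponds to 4.0 × 10⁶ cells/mL.
    """
    if od < 0:
        raise ValueError("OD must be non-negative")
    return od * (cells_ref / od_ref)
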