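"""Temperature–mortality exposure-response functions (ERFs).

An ERF maps daily mean temperature to a relative mortality risk RR for
one adult age group, with RR = 1 at the minimum mortality temperature
(MMT).  Curves arrive as lag-cumulative log-RR coefficients on a grid of
relative temperature percentiles and are translated to absolute
temperature using a city's domain-average daily temperature series: knot
temperatures are the empirical quantiles of that series at the curve's
percentiles (linear interpolation between order statistics, the single
supported quantile rule so results are bit-reproducible).

Between knots, log-RR is interpolated with a monotone-shape-preserving
cubic (PCHIP), which cannot introduce spurious risk dips between knots; a
piecewise-linear alternative is available for curves that are linear by
construction.  Outside the observed temperature range RR is clamped to
its boundary value: risk is quantified only at the extremes actually
observed, never extrapolated beyond them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

AGE_GROUPS = ("20-44", "45-64", "65-74", "75-84", "85+")

Interpolation = Literal["pchip", "linear"]

__all__ = [
    "AGE_GROUPS",
    "PercentileCurve",
    "ERFCurve",
    "ERFEnsemble",
    "calibrate_to_temperature",
]


@dataclass(frozen=True)
class PercentileCurve:
    """Log-RR coefficients on a strictly ascending percentile grid in
    [0, 100] for one age group."""

    age_group: str
    percentiles: np.ndarray
    log_rr: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        lr = np.asarray(self.log_rr, dtype=float)
        object.__setattr__(self, "percentiles", p)
        object.__setattr__(self, "log_rr", lr)
        if p.ndim != 1 or p.shape != lr.shape:
            raise ValueError("percentiles and log_rr must be 1-D arrays of equal length")
        if np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly ascending")
        if p[0] < 0 or p[-1] > 100:
            raise ValueError("percentiles must lie in [0, 100]")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(lr))):
            raise ValueError("non-finite percentile curve")


@dataclass
class ERFCurve:
    """Calibrated exposure-response curve in absolute temperature.

    ``knot_temperatures`` are strictly ascending °C; ``log_rr_at_knots``
    is recentred so RR at the located MMT equals 1.  ``observed_range``
    is the (min, max) of the calibration series and bounds evaluation.
    """

    age_group: str
    knot_temperatures: np.ndarray
    log_rr_at_knots: np.ndarray
    observed_range: tuple[float, float]
    interpolation: Interpolation = "pchip"
    mmt: float | None = None
    rr_tmin: float | None = field(default=None, repr=False)
    rr_tmax: float | None = field(default=None, repr=False)
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        kt = np.asarray(self.knot_temperatures, dtype=float)
        lr = np.asarray(self.log_rr_at_knots, dtype=float)
        if kt.ndim != 1 or kt.shape != lr.shape or kt.size < 2:
            raise ValueError("need >= 2 matching knots")
        if np.any(np.diff(kt) <= 0):
            raise ValueError("knot temperatures must be strictly ascending")
        lo, hi = self.observed_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("observed_range must be a finite, non-degenerate interval")
        self.knot_temperatures = kt
        self.log_rr_at_knots = lr
        self._rebuild()

    def _rebuild(self) -> None:
        if self.interpolation == "pchip":
            self._interp = PchipInterpolator(
                self.knot_temperatures, self.log_rr_at_knots, extrapolate=True
            )
        elif self.interpolation == "linear":
            kt, lr = self.knot_temperatures, self.log_rr_at_knots
            self._interp = lambda t: np.interp(t, kt, lr)
        else:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    # -- evaluation ---------------------------------------------------------

    def log_rr(self, t: float | np.ndarray) -> np.ndarray | float:
        """Interpolated log relative risk, clamped to the observed range
        (constant extrapolation at the boundary values)."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature")
        lo = max(self.observed_range[0], self.knot_temperatures[0])
        hi = min(self.observed_range[1], self.knot_temperatures[-1])
        tc = np.clip(t, lo, hi)
        out = self._interp(tc)
        return out if out.ndim else float(out)

    def rr(self, t: float | np.ndarray) -> np.ndarray | float:
        """Relative risk RR(t) = exp(log-RR(t)); always positive."""
        return np.exp(self.log_rr(t))

    def find_mmt(self, resolution: float = 0.1) -> float:
        """Grid-search the observed range for the temperature of minimum
        risk; exact ties break toward the warmer candidate."""
        lo, hi = self.observed_range
        n = max(int(np.ceil((hi - lo) / resolution)) + 1, 2)
        grid = np.linspace(lo, hi, n)
        vals = np.asarray(self.log_rr(grid))
        # argmin on the reversed array → last (warmest) index attaining the min
        idx = len(vals) - 1 - int(np.argmin(vals[::-1]))
        return float(grid[idx])

    def recentre(self, resolution: float = 0.1) -> "ERFCurve":
        """Locate the MMT and shift log-RR so RR(MMT) = 1; caches the MMT
        and the relative risks at the observed extremes."""
        mmt = self.find_mmt(resolution)
        shift = float(self.log_rr(mmt))
        cur = replace(
            self,
            log_rr_at_knots=self.log_rr_at_knots - shift,
            mmt=mmt,
            rr_tmin=None,
            rr_tmax=None,
        )
        cur.rr_tmin = float(cur.rr(cur.observed_range[0]))
        cur.rr_tmax = float(cur.rr(cur.observed_range[1]))
        return cur

    def extreme_rrs(self) -> tuple[float, float]:
        """(RR at the coldest, RR at the warmest) observed extreme."""
        if self.rr_tmin is None or self.rr_tmax is None:
            return float(self.rr(self.observed_range[0])), float(self.rr(self.observed_range[1]))
        return self.rr_tmin, self.rr_tmax


@dataclass
class ERFEnsemble:
    """A central curve plus Monte-Carlo uncertainty draws (all one age
    group); draw 0 by convention is the central curve."""

    central: ERFCurve
    draws: list[ERFCurve]

    def __post_init__(self) -> None:
        if len(self.draws) < 1:
            raise ValueError("ensemble needs at least one draw")
        for d in self.draws:
            if d.age_group != self.central.age_group:
                raise ValueError("all draws must share the central curve's age group")

    @property
    def age_group(self) -> str:
        return self.central.age_group

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def calibrate_to_temperature(
    pc: PercentileCurve,
    reference_series: pd.Series | np.ndarray,
    interpolation: Interpolation = "pchip",
    mmt_resolution: float = 0.1,
) -> ERFCurve:
    """Translate a percentile-space curve to absolute temperature.

    Knot temperatures are the empirical quantiles of ``reference_series``
    at the curve's percentiles; the observed range is the series min/max;
    the curve is recentred so RR = 1 at its MMT.

    Raises on series shorter than 100 days, non-finite values, or a
    degenerate (e.g. constant) series whose quantiles collide.
    """
    series = np.asarray(
        reference_series.values if isinstance(reference_series, pd.Series) else reference_series,
        dtype=float,
    )
    if series.size < 100:
        raise ValueError(f"reference series too short ({series.size} days; need >= 100)")
    if not np.all(np.isfinite(series)):
        raise ValueError("reference series contains non-finite temperatures")
    knots = np.quantile(series, pc.percentiles / 100.0, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate quantiles: reference series yields non-ascending knots")
    curve = ERFCurve(
        age_group=pc.age_group,
        knot_temperatures=knots,
        log_rr_at_knots=pc.log_rr.copy(),
        observed_range=(float(series.min()), float(series.max())),
        interpolation=interpolation,
    )
    return curve.recentre(mmt_resolution)
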