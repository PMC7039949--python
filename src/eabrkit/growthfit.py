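"""Growth-function and strength-duration fitting.

Growth functions (wave amplitude vs charge or current) are fitted with
either a straight line or a continuous two-segment "broken stick" whose
parameters are box-bounded: slope of line 1 in [0.1, 50] uV/nC, slope of
line 2 in [-2, 0] uV/nC (saturation forced flat or declining), intercept
of line 1 in [-10, 2] uV, and knee in [2, 20] nC.  Model choice is
automated by an extra-sum-of-squares F-test with a manual override.

Strength-duration functions regress threshold (dB) on log2(phase
duration), yielding a slope in dB per doubling; a perfect charge
integrator has slope 0 dB re 1 nC per doubling, and the charge-basis and
current-basis slopes always differ by exactly 20*log10(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .quantify import CRITERION_UV, GrowthSeries, to_db

__all__ = [
    "GrowthFitResult",
    "SDFitResult",
    "BROKEN_STICK_BOUNDS",
    "fit_linear",
    "fit_broken_stick",
    "select_model",
    "strength_duration_fit",
    "broken_stick_model",
]

#: Printed parameter bounds for the broken-stick fit (charge basis).
BROKEN_STICK_BOUNDS = {
    "slope1": (0.1, 50.0),  # uV/nC
    "slope2": (-2.0, 0.0),  # uV/nC
    "intercept1": (-10.0, 2.0),  # uV
    "knee": (2.0, 20.0),  # nC
}
N_KNEE_STARTS = 9


@dataclass(frozen=True)
class GrowthFitResult:
    model: str  # "linear" or "broken_stick"
    slope1: float
    intercept1: float
    r_squared: float
    n_points: int
    ssr: float
    basis: str = "charge"
    slope2: float | None = None
    knee: float | None = None
    x_min: float = float("nan")
    x_max: float = float("nan")
    low_n: bool = False
    at_bounds: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            return self.intercept1 + self.slope1 * x
        return broken_stick_model(x, self.slope1, self.intercept1,
                                  self.slope2, self.knee)


def broken_stick_model(
    x: np.ndarray, slope1: float, intercept1: float, slope2: float, knee: float
) -> np.ndarray:
    """Continuous two-segment line with a knee."""
    x = np.asarray(x, dtype=float)
    y1 = intercept1 + slope1 * x
    y2 = intercept1 + slope1 * knee + slope2 * (x - knee)
    return np.where(x <= knee, y1, y2)


def _series_xy(
    series: GrowthSeries, basis: str, criterion_uv: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Suprathreshold (x, y) points and the charge-per-current factor."""
    if basis not in ("charge", "current"):
        raise ValueError("basis must be 'charge' or 'current'")
    charges = series.charges()
    currents = series.currents()
    amps = series.amplitudes()
    supra = amps > criterion_uv
    factor = float(np.median(charges / currents))  # nC per uA, constant per shape
    x = charges[supra] if basis == "charge" else currents[supra]
    return x, amps[supra], factor

def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(
    series: GrowthSeries,
    basis: str = "charge",
    criterion_uv: float = CRITERION_UV,
) -> GrowthFitResult:
    """Ordinary least squares of amplitude on charge (or current)."""
    x, y, _ = _series_xy(series, basis, criterion_uv)
    if x.size < 2:
        raise ValueError("fit_linear needs at least 2 suprathreshold levels")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return GrowthFitResult(
        model="linear",
        slope1=float(slope),
        intercept1=float(intercept),
        r_squared=_r_squared(y, resid),
        n_points=int(x.size),
        ssr=float(np.sum(resid**2)),
        basis=basis,
        x_min=float(x.min()),
        x_max=float(x.max()),
        low_n=x.size == 2,
    )


def _scaled_bounds(basis: str, factor_nc_per_ua: float) -> dict:
    """Bounds rescaled from the charge basis to the requested basis."""
    b = BROKEN_STICK_BOUNDS
    if basis == "charge":
        return dict(b)
    f = factor_nc_per_ua
    return {
        "slope1": (b["slope1"][0] * f, b["slope1"][1] * f),
        "slope2": (b["slope2"][0] * f, b["slope2"][1] * f),
        "intercept1": b["intercept1"],
        "knee": (b["knee"][0] / f, b["knee"][1] / f),
    }


def fit_broken_stick(
    series: GrowthSeries,
    basis: str = "charge",
    criterion_uv: float = CRITERION_UV,
) -> GrowthFitResult:
    """Bounded nonlinear least squares of the two-segment model.

    Deterministic multi-start over a grid of knee candidates; the best
    (lowest SSR) solution is returned.
    """
    x, y, factor = _series_xy(series, basis, criterion_uv)
    if x.size < 4:
        raise ValueError("fit_broken_stick needs at least 4 suprathreshold levels")
    bounds = _scaled_bounds(basis, factor)
    lo = np.array([bounds["slope1"][0], bounds["intercept1"][0],
                   bounds["slope2"][0], bounds["knee"][0]])
    hi = np.array([bounds["slope1"][1], bounds["intercept1"][1],
                   bounds["slope2"][1], bounds["knee"][1]])

    s0, i0 = np.polyfit(x, y, 1)
    s0 = float(np.clip(s0, *bounds["slope1"]))
    i0 = float(np.clip(i0, *bounds["intercept1"]))

    def resid(theta):
        return broken_stick_model(x, theta[0], theta[1], theta[2], theta[3]) - y

    best = None
    knee_grid = np.linspace(bounds["knee"][0], bounds["knee"][1], N_KNEE_STARTS)
    for knee0 in knee_grid:
        theta0 = np.clip([s0, i0, -1e-6, knee0], lo, hi)
        sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    s1, i1, s2, knee = best.x
    r = resid(best.x)
    eps = 1e-6
    at_bounds = bool(
        knee <= bounds["knee"][0] + eps or knee >= bounds["knee"][1] - eps
    )
    return GrowthFitResult(
        model="broken_stick",
        slope1=float(s1),
        intercept1=float(i1),
        slope2=float(min(s2, 0.0)),
        knee=float(knee),
        r_squared=_r_squared(y, r),
        n_points=int(x.size),
        ssr=float(np.sum(r**2)),
        basis=basis,
        x_min=float(x.min()),
        x_max=float(x.max()),
        at_bounds=at_bounds,
    )


def select_model(
    linear_fit: GrowthFitResult,
    broken_fit: GrowthFitResult,
    alpha: float = 0.05,
    override: str | None = None,
) -> GrowthFitResult:
    """Automated replacement for by-eye model choice.

    The broken stick is preferred iff the extra-sum-of-squares F-test is
    significant at ``alpha`` AND the fitted knee lies strictly inside the
    tested range.  ``override`` ('linear' or 'broken_stick') wins
    unconditionally.
    """
    if override == "linear":
        return linear_fit
    if override == "broken_stick":
        return broken_fit
    if override is not None:
        raise ValueError(f"unknown override {override!r}")
    n = broken_fit.n_points
    if n <= 4 or broken_fit.ssr <= 0:
        return linear_fit
    df_extra = 2  # knee + second slope
    f_stat = ((linear_fit.ssr - broken_fit.ssr) / df_extra) / (
        broken_fit.ssr / (n - 4)
    )
    p = float(stats.f.sf(max(f_stat, 0.0), df_extra, n - 4))
    knee_interior = (
        broken_fit.knee is not None
        and broken_fit.x_min < broken_fit.knee < broken_fit.x_max
    )
    if p < alpha and knee_interior:
        return broken_fit
    return linear_fit


@dataclass(frozen=True)
class SDFitResult:
    slope_db_per_doubling: float
    intercept_db: float
    r_squared: float
    basis: str  # "dB re 1 nC" or "dB re 1 uA"
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")


def strength_duration_fit(
    thresholds: Mapping[float, float | None],
    basis: str = "dB re 1 nC",
) -> SDFitResult:
    """Regress threshold (dB) on log2(phase duration).

    ``thresholds`` maps phase duration (us) to a threshold (nC or uA
    matching ``basis``); undefined (None) thresholds are dropped.
    """
    pairs = [(d, t) for d, t in thresholds.items() if t is not None]
    if len(pairs) < 2:
        raise ValueError("need >= 2 durations with defined thresholds")
    pairs.sort()
    x = np.array([math.log2(d) for d, _ in pairs])
    y = np.array([to_db(t) for _, t in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return SDFitResult(
        slope_db_per_doubling=float(slope),
        intercept_db=float(intercept),
        r_squared=min(r2, 1.0),
        basis=basis,
        n_points=len(pairs),
    )
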