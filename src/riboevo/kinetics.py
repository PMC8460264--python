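"""Kinetic model fitting for primer-extension and ligation time courses.

Three models cover the measurements made on the polymerase and its products:

* burst + single exponential rise to maximum,
  ``F(t) = A_b + A_s * (1 - exp(-k_obs * t))`` — primer extension where a
  subpopulation reacts within the first seconds (the burst amplitude
  ``A_b``) and the remainder follows first-order kinetics at ``k_obs``;
* linear initial rate — mean nucleotides added during the first seconds of
  the reaction, slope in nt per minute;
* linear fraction-vs-time — slow ligation time courses, slope per hour.

Time units are explicit on every time course (s, min, or hr); fitting is
done on an internal canonical scale of minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_TO_MINUTES = {"s": 1.0 / 60.0, "min": 1.0, "hr": 60.0}

__all__ = [
    "TimeCourse",
    "KineticFit",
    "RateComparison",
    "burst_model",
    "fit_burst_exponential",
    "fit_initial_rate",
    "fit_linear_rate",
    "rate_acceleration",
]


@dataclass(frozen=True)
class TimeCourse:
    """Observed reaction progress at a series of times.

    ``kind`` is "fraction" (fraction of primers extended/ligated, in [0,1])
    or "mean_nt" (mean nucleotides added, >= 0). ``unit`` applies to every
    time value.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]
    unit: str
    kind: str = "fraction"
    label: str = ""

    def __post_init__(self) -> None:
        if self.unit not in _TO_MINUTES:
            raise ValueError(f"unknown time unit {self.unit!r} (use s, min, hr)")
        if self.kind not in ("fraction", "mean_nt"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if len(self.times) != len(self.values):
            raise ValueError("times and values differ in length")
        t = np.asarray(self.times)
        if (t < 0).any() or (np.diff(t) <= 0).any():
            raise ValueError("times must be non-negative and strictly increasing")
        v = np.asarray(self.values)
        if self.kind == "fraction" and ((v < 0) | (v > 1)).any():
            raise ValueError("fraction values must lie in [0, 1]")
        if self.kind == "mean_nt" and (v < 0).any():
            raise ValueError("mean_nt values must be >= 0")

    def minutes(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float) * _TO_MINUTES[self.unit]


@dataclass(frozen=True)
class KineticFit:
    """Fitted parameters of a kinetic model with residual diagnostics."""

    model: str  # burst_exponential | exponential | linear
    burst_amplitude: float = 0.0
    slow_amplitude: float = 0.0
    k_obs: float = float("nan")  # per minute
    slope: float = float("nan")  # per minute (linear models)
    intercept: float = float("nan")
    rss: float = float("nan")
    n: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def predict(self, t_minutes: np.ndarray) -> np.ndarray:
        t = np.asarray(t_minutes, dtype=float)
        if self.model == "linear":
            return self.intercept + self.slope * t
        return burst_model(t, self.burst_amplitude, self.slow_amplitude, self.k_obs)

    def value_at(self, time: float, unit: str = "min") -> float:
        """Model evaluation at one time point (e.g. fraction extended at 10 s)."""
        return float(self.predict(np.array([time * _TO_MINUTES[unit]]))[0])


def burst_model(t: np.ndarray, a_burst: float, a_slow: float, k_obs: float) -> np.ndarray:
    """F(t) = A_b + A_s * (1 - exp(-k_obs * t)), t in minutes."""
    return a_burst + a_slow * (1.0 - np.exp(-k_obs * t))


def fit_burst_exponential(tc: TimeCourse, fix_burst_zero: bool = False) -> KineticFit:
    """Least-squares fit of the burst + single-exponential model.

    Initialization: A_b from the earliest observation, A_s from the rise to
    the final observation, k_obs from the interpolated half-rise time, with
    multi-start over k_obs x {0.1, 1, 10} to escape flat regions of the
    objective. Bounds keep all parameters non-negative and A_b + A_s <= 1.1.
    ``fix_burst_zero`` reduces the model to a plain exponential.
    """
    if tc.kind != "fraction":
        raise ValueError("burst model fits fraction-extended data")
    t = tc.minutes()
    y = np.asarray(tc.values, dtype=float)
    if len(t) < (3 if fix_burst_zero else 4):
        raise ValueError("too few points for the number of parameters")

    a_b0 = max(y[0], 0.0)
    a_s0 = max(y[-1] - a_b0, 1e-3)
    half = a_b0 + 0.5 * a_s0
    above = np.nonzero(y >= half)[0]
    t_half = t[above[0]] if len(above) and t[above[0]] > 0 else max(t[-1] / 2, 1e-3)
    k0 = math.log(2.0) / t_half

    def residuals_full(p: np.ndarray) -> np.ndarray:
        return burst_model(t, p[0], p[1], p[2]) - y

    def residuals_noburst(p: np.ndarray) -> np.ndarray:
        return burst_model(t, 0.0, p[0], p[1]) - y

    best = None
    for k_start in (0.1 * k0, k0, 10.0 * k0):
        if fix_burst_zero:
            x0 = np.array([max(a_s0 + a_b0, 1e-3), k_start])
            lb, ub = [0.0, 1e-9], [1.1, np.inf]
            fun = residuals_noburst
        else:
            x0 = np.array([a_b0, a_s0, k_start])
            lb, ub = [0.0, 0.0, 1e-9], [1.1, 1.1, np.inf]
            fun = residuals_full
        sol = optimize.least_squares(
            fun, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    if not best.success and best.cost > 1e-6:
        raise RuntimeError(f"burst fit did not converge: {best.message}")
    if fix_burst_zero:
        a_b, (a_s, k) = 0.0, best.x
        model = "exponential"
    else:
        a_b, a_s, k = best.x
        model = "burst_exponential"
    return KineticFit(
        model=model,
        burst_amplitude=float(a_b),
        slow_amplitude=float(a_s),
        k_obs=float(k),
        rss=float(2 * best.cost),
        n=len(t),
    )


def _ols_slope(t_min: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b*t; returns (slope, intercept, rss)."""
    coeffs, res, *_ = np.polyfit(t_min, y, 1, full=True)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    rss = float(res[0]) if len(res) else 0.0
    return slope, intercept, rss


def fit_initial_rate(tc: TimeCourse, window: tuple[float, float] | None = None) -> KineticFit:
    """Initial-phase slope by ordinary least squares, intercept free.

    ``window`` is (start, end) in the time course's own unit; default is the
    full range. For mean-nucleotides-added data the slope is the average
    rate of NTP addition in nt per minute.
    """
    t_raw = np.asarray(tc.times, dtype=float)
    if window is None:
        mask = np.ones_like(t_raw, dtype=bool)
    else:
        mask = (t_raw >= window[0]) & (t_raw <= window[1])
    if mask.sum() < 2:
        raise ValueError("need at least 2 points inside the window")
    t = tc.minutes()[mask]
    y = np.asarray(tc.values, dtype=float)[mask]
    slope, intercept, rss = _ols_slope(t, y)
    return KineticFit(model="linear", slope=slope, intercept=intercept, rss=rss, n=int(mask.sum()))


def fit_linear_rate(tc: TimeCourse, window: tuple[float, float] | None = None) -> float:
    """Slope of fraction-reacted vs. time within the linear regime, per hour."""
    if tc.kind != "fraction":
        raise ValueError("linear ligation rate fits fraction data")
    fit = fit_initial_rate(tc, window=window)
    return fit.slope * 60.0  # per minute -> per hour


def _round_sigfigs(x: float, sigfigs: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sigfigs - 1))


@dataclass(frozen=True)
class RateComparison:
    """Catalyzed vs. uncatalyzed rate, as a rounded fold acceleration."""

    k_cat: float
    k_uncat: float
    unit: str
    fold: float
    fold_sigfigs: int


def rate_acceleration(
    k_cat: float,
    k_uncat: float,
    unit: str = "hr^-1",
    uncat_unit: str | None = None,
    sigfigs: int = 2,
) -> RateComparison:
    """Fold rate acceleration of the catalyzed over the uncatalyzed reaction.

    Both rates must carry the same unit; the fold ratio is rounded to
    ``sigfigs`` significant figures (the convention used when quoting rate
    accelerations).
    """
    if uncat_unit is not None and uncat_unit != unit:
        raise ValueError(f"unit mismatch: {unit!r} vs {uncat_unit!r}")
    if k_uncat <= 0:
        raise ValueError("uncatalyzed rate must be positive")
    fold = _round_sigfigs(k_cat / k_uncat, sigfigs)
    return RateComparison(k_cat, k_uncat, unit, fold, sigfigs)
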