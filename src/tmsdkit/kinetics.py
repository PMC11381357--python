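"""Fluorescence kinetics: calibration, second-order rate fits, rate classes,
and Arrhenius apparent activation energies.

The reaction I + QF -> IF + Q is monitored by fluorescence unquenching and
fitted with the equal-concentration irreversible second-order law

    c(t) = c0^2 k t / (1 + c0 k t),

where c is the product (IF) concentration and c0 the common initial
concentration of invader and substrate duplex (50 nM by default, a 1:1 mix
of 100 nM stocks).  The time to reach a completion fraction f* (default
0.95) defines the three rate classes: < 1000 s -> class 0, 1000-3600 s ->
class 1 (closed interval), > 3600 s -> class 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "R_GAS",
    "CalibrationCurve",
    "KineticTrace",
    "RateFit",
    "ArrheniusFit",
    "fit_standard_curve",
    "trace_to_concentration",
    "second_order_progress",
    "fit_rate_constant",
    "fit_replicates",
    "time_to_equilibrium",
    "classify_rate",
    "arrhenius_fit",
]

R_GAS = 8.314  # J/(mol K)

#: rate-class boundaries on the time to equilibrium, seconds
CLASS_BOUNDARIES = (1000.0, 3600.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: intensity = slope * concentration(nM) + intercept."""

    slope: float  # a.u. per nM
    intercept: float  # a.u.
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class KineticTrace:
    """One fluorescence time series at a fixed temperature."""

    times: np.ndarray  # s
    intensities: np.ndarray  # a.u.
    temperature: float = 25.0  # deg C
    sample_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if times.shape != intensities.shape or times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if times.size and times[0] < 0:
            raise ValueError("times must start at or after 0")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)


@dataclass(frozen=True)
class RateFit:
    """Second-order fit of one concentration trace."""

    k: float  # 1/(M s)
    c0: float  # M
    sse: float
    t_eq: float  # s, time to the f* completion fraction (inf if k == 0)
    rate_class: int  # 0 fast | 1 medium | 2 slow
    no_reaction: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant must be nonnegative")


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = lnA - Ea/(R T) over a small set of temperatures."""

    ea: float  # J/mol
    ln_a: float
    r_squared: float
    n_temperatures: int

    def __post_init__(self) -> None:
        if self.n_temperatures < 2:
            raise ValueError("Arrhenius fit needs at least 2 temperatures")


def fit_standard_curve(
    concs_nm: Sequence[float], intensities: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration nM, intensity)."""
    x = np.asarray(concs_nm, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and intensity lists differ in length")
    if np.unique(x).size < 2:
        raise ValueError("standard curve needs at least 2 distinct concentrations")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def trace_to_concentration(
    trace: KineticTrace, calib: CalibrationCurve, background: float
) -> np.ndarray:
    """Convert intensities to product concentration in M (clipped at 0)."""
    if calib.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc_nm = (trace.intensities - background - calib.intercept) / calib.slope
    return np.clip(conc_nm, 0.0, None) * 1e-9


def second_order_progress(t: np.ndarray, k: float, c0: float) -> np.ndarray:
    """Product concentration under the equal-concentration second-order law."""
    kt = k * c0 * np.asarray(t, dtype=float)
    return c0 * kt / (1.0 + kt)


def _initial_guess(times: np.ndarray, conc: np.ndarray, c0: float) -> float:
    """k0 from the half-completion time; grid search over log10 k fallback."""
    half = c0 / 2.0
    above = np.nonzero(conc >= half)[0]
    if above.size and times[above[0]] > 0:
        return 1.0 / (c0 * times[above[0]])
    grid = np.logspace(2, 8, 61)
    sses = [float(np.sum((second_order_progress(times, k, c0) - conc) ** 2)) for k in grid]
    return float(grid[int(np.argmin(sses))])


def fit_rate_constant(
    times: Sequence[float],
    conc: Sequence[float],
    c0: float,
    f_star: float = 0.95,
) -> RateFit:
    """Nonlinear least-squares fit of the second-order rate constant.

    A flat trace at zero concentration is reported as k = 0 with the
    no-reaction flag; non-convergence is flagged rather than raised.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 5:
        raise ValueError("rate fit needs at least 5 points")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if np.max(conc) < 1e-4 * c0:
        return RateFit(
            k=0.0, c0=c0, sse=float(np.sum(conc**2)), t_eq=math.inf,
            rate_class=2, no_reaction=True,
        )
    k0 = _initial_guess(times, conc, c0)
    # fit log10 k against the dimensionless progress curve: both are O(1),
    # whereas molar residuals (~1e-9) would stall the optimizer's tolerances
    frac = conc / c0

    def residuals(z: np.ndarray) -> np.ndarray:
        kt = 10.0 ** z[0] * c0 * times
        return kt / (1.0 + kt) - frac

    result = optimize.least_squares(
        residuals, x0=[math.log10(k0)], bounds=(-6.0, 12.0), xtol=1e-14, ftol=1e-14
    )
    converged = bool(result.success)
    k = float(10.0 ** result.x[0]) if converged else k0
    sse = float(np.sum((second_order_progress(times, k, c0) - conc) ** 2))
    t_eq = time_to_equilibrium(k, c0, f_star) if k > 0 else math.inf
    return RateFit(
        k=k, c0=c0, sse=sse, t_eq=t_eq,
        rate_class=classify_rate(t_eq), converged=converged,
    )


def fit_replicates(fits: Sequence[RateFit]) -> float:
    """Combine parallel-experiment fits as a geometric mean of k.

    Rate constants span orders of magnitude, so averaging happens on the
    log scale.  No-reaction replicates are excluded; all-flat input gives 0.
    """
    ks = [f.k for f in fits if f.k > 0 and not f.no_reaction]
    if not ks:
        return 0.0
    return float(np.exp(np.mean(np.log(ks))))


def time_to_equilibrium(k: float, c0: float, f_star: float = 0.95) -> float:
    """Time for the reaction to reach completion fraction f*."""
    if k <= 0:
        raise ValueError("time to equilibrium requires k > 0")
    if not 0.0 < f_star < 1.0:
        raise ValueError("f_star must lie in (0, 1)")
    return f_star / ((1.0 - f_star) * k * c0)


def classify_rate(
    t_eq: float, boundaries: tuple[float, float] = CLASS_BOUNDARIES
) -> int:
    """Three rate classes from the time to equilibrium.

    t < fast boundary -> 0; fast <= t <= slow (closed interval) -> 1;
    t > slow boundary -> 2.
    """
    t_fast, t_slow = boundaries
    if not 0 < t_fast < t_slow:
        raise ValueError("boundaries must satisfy 0 < t_fast < t_slow")
    if t_eq < t_fast:
        return 0
    if t_eq <= t_slow:
        return 1
    return 2


def arrhenius_fit(k_by_temp_c: Mapping[float, float]) -> ArrheniusFit:
    """Apparent activation energy from ln k vs 1/T(K) least squares."""
    if len(k_by_temp_c) < 2:
        raise ValueError("Arrhenius fit needs at least 2 temperatures")
    temps = np.array(sorted(k_by_temp_c), dtype=float)
    ks = np.array([k_by_temp_c[t] for t in temps], dtype=float)
    if np.any(ks <= 0):
        raise ValueError("Arrhenius fit requires positive rate constants")
    inv_t = 1.0 / (temps + 273.15)
    ln_k = np.log(ks)
    res = stats.linregress(inv_t, ln_k)
    r2 = float(res.rvalue**2) if np.std(ln_k) > 0 else 1.0
    return ArrheniusFit(
        ea=float(-res.slope * R_GAS),
        ln_a=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_temperatures=len(temps),
    )
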