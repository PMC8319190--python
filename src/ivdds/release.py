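"""In-vitro release characterization of triggered drug delivery systems.

A temperature-sensitive liposome (TSL) releases its payload at an
approximately constant (zero-order) rate during the short residence time
of a microvascular pass.  The release time ``t_rel`` is the extrapolated
time to complete release under that zero-order assumption: a linear fit
of percent release against time over a short early window gives a slope
``m`` (%/s), and ``t_rel = 100 / m``.  A table of ``t_rel`` versus assay
temperature, interpolated with a shape-preserving cubic, converts the
measured tissue temperature into the fractional release rate
``1/t_rel`` driving the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import CalibrationError, ConfigurationError, InputError, NoReleaseError

#: Default early-window lengths (s) for the slope fit: slow and fast
#: formulations stay linear for ~10 s and ~4 s respectively.
DEFAULT_WINDOW_SLOW = 10.0
DEFAULT_WINDOW_FAST = 4.0


@dataclass
class InVitroReleaseTrace:
    """Raw fluorescence release assay at a single temperature.

    ``Fl_b`` is the background (pre-trigger) fluorescence, ``Fl_m`` the
    100%-release fluorescence after detergent lysis.
    """

    times: np.ndarray          # s, strictly increasing
    Fl_n: np.ndarray           # raw fluorescence, a.u.
    Fl_b: float
    Fl_m: float
    temperature: Optional[float] = None   # deg C

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Fl_n = np.asarray(self.Fl_n, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.Fl_n.shape:
            raise InputError("times and Fl_n must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if not self.Fl_m > self.Fl_b:
            raise CalibrationError(
                f"Fl_m ({self.Fl_m}) must exceed Fl_b ({self.Fl_b})")

    def percent(self) -> np.ndarray:
        return percent_release(self.Fl_n, self.Fl_b, self.Fl_m)


@dataclass
class ReleaseTable:
    """Release time as a function of temperature for one formulation."""

    temperatures: np.ndarray     # deg C, strictly increasing
    t_rel: np.ndarray            # s, > 0
    label: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.t_rel = np.asarray(self.t_rel, dtype=float)
        if self.temperatures.size == 0:
            raise ConfigurationError("release table is empty")
        if self.temperatures.shape != self.t_rel.shape:
            raise ConfigurationError("temperature and t_rel columns differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ConfigurationError("temperatures must be strictly increasing")
        if np.any(self.t_rel <= 0):
            raise ConfigurationError("all t_rel entries must be > 0")
        if np.any(np.diff(self.t_rel) > 0):
            warnings.warn(
                f"release table {self.label!r}: t_rel increases with temperature "
                "somewhere; release normally accelerates when heated",
                stacklevel=2)


def percent_release(Fl_n, Fl_b: float, Fl_m: float):
    """Release (%) = (Fl_n - Fl_b) / (Fl_m - Fl_b) * 100.

    Not clipped to [0, 100]; noisy inputs may stray outside and callers
    decide whether to clip.
    """
    if not Fl_m > Fl_b:
        raise CalibrationError(f"Fl_m ({Fl_m}) must exceed Fl_b ({Fl_b})")
    return (np.asarray(Fl_n, dtype=float) - Fl_b) / (Fl_m - Fl_b) * 100.0


def estimate_release_time(trace: InVitroReleaseTrace, window_s: float) -> float:
    """Zero-order release time from a windowed linear fit.

    Ordinary least squares of percent release against time over
    ``[0, window_s]`` (intercept free); ``t_rel = 100 / slope``.  This is
    the extrapolated time to complete release at the initial rate, not
    the empirical time at which the trace reaches 100%.
    """
    mask = trace.times <= window_s
    if np.count_nonzero(mask) < 3:
        raise InputError(
            f"window {window_s} s covers {np.count_nonzero(mask)} samples; need >= 3")
    t = trace.times[mask]
    pct = trace.percent()[mask]
    slope, _ = np.polyfit(t, pct, 1)
    if slope <= 0:
        raise NoReleaseError(
            f"non-positive release slope ({slope:.3g} %/s); t_rel undefined")
    return 100.0 / slope


class ReleaseRateModel:
    """Temperature -> zero-order fractional release rate (1/s).

    ``t_rel(T)`` is interpolated with a monotone shape-preserving
    piecewise cubic (PCHIP) and inverted to a rate.  Below the lowest
    tabulated temperature the trigger is absent and the rate is 0; above
    the highest, the rate is clamped at the highest-temperature value.
    """

    def __init__(self, table: ReleaseTable):
        self.table = table
        if table.temperatures.size >= 2:
            self._interp = PchipInterpolator(table.temperatures, table.t_rel)
        else:
            self._interp = None
        self.T_min = float(table.temperatures[0])
        self.T_max = float(table.temperatures[-1])
        self._rate_max_T = 1.0 / float(table.t_rel[-1])

    def t_rel(self, T):
        """Interpolated release time (s); NaN below range (no release)."""
        T = np.asarray(T, dtype=float)
        if self._interp is None:
            out = np.full(T.shape, float(self.table.t_rel[0]))
        else:
            out = self._interp(np.clip(T, self.T_min, self.T_max))
        return np.where(T < self.T_min, np.nan, out)

    def rate(self, T):
        """Fractional release rate 1/t_rel (1/s); 0 below the table range."""
        T = np.asarray(T, dtype=float)
        scalar = T.ndim == 0
        T = np.atleast_1d(T)
        if self._interp is None:
            r = np.full(T.shape, 1.0 / float(self.table.t_rel[0]))
        else:
            r = 1.0 / self._interp(np.clip(T, self.T_min, self.T_max))
        r = np.where(T < self.T_min, 0.0, r)
        return float(r[0]) if scalar else r


def release_rate_at_temperature(table: ReleaseTable, T) -> float:
    """Convenience wrapper: zero-order fractional release rate at ``T``."""
    return ReleaseRateModel(table).rate(T)
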