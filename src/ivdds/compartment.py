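"""Coupled compartmental dynamics of triggered intravascular delivery.

Four well-mixed pools are integrated in time: tumor EES free drug
(``c_e_T``), systemic plasma free drug (``c_p_S``), systemic tissue free
drug (``c_t_S``) and systemic plasma encapsulated drug (``c_p_DDS_S``),
plus a cumulative eliminated-mass ledger.  The tumor microvasculature is
*not* well mixed: at every solver evaluation the quasi-steady capillary
gradient (:mod:`ivdds.gradient`) is re-solved with the instantaneous
release rate ``r = TT / t_rel(T(t))`` obtained from the measured tissue
temperature and the in-vitro release table.  Release is gated purely by
that rate (zero below the lowest tabulated temperature), so no separate
heating on/off switch exists.

The governing equations:

* dc_e_T/dt   = (F_p / v_e_av) * c_extr(x=1)
* dc_p_S/dt   = exchange(c_p_T(x=1) - c_p_S) - (k_e + k_p) c_p_S + k_t c_t_S
* dc_t_S/dt   = k_p c_p_S - k_t c_t_S
* dc_dds_S/dt = (Q / V_p_S) (c_dds_T(x=1) - c_dds_S)

with ``Q = V_p_T * F_p / v_p`` the tumor plasma volumetric flow (equal
to ``V_p_T / TT`` when the perfusion is the derived value).  The exchange
term dilutes the amount flux ``Q * dc`` into a systemic volume; see
``f_distr_mode`` below for the three supported readings.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputError, IntegrationError, InvalidParameterError
from .gradient import GradientEndpoint, GradientInputs, solve_endpoint
from .params import DoseSpec, ParameterBundle
from .release import ReleaseRateModel, ReleaseTable

log = logging.getLogger(__name__)

#: Supported dilution-volume conventions for the tumor->systemic exchange
#: term.  "mass": amount flux divided by the initial distribution volume
#: V_D in both flow directions; with the ledger carried on a V_D basis
#: this conserves mass exactly.  "switching": V_D when the net flux runs
#: tumor->systemic, systemic plasma volume V_p_S otherwise.  "as_printed":
#: the (V_p_T/V_p_S) prefactor multiplied by f_distr = V_p_T/V_D for
#: tumor->systemic flux and 1 otherwise.  The last two do not conserve
#: the V_D-basis ledger exactly.
F_DISTR_MODES = ("mass", "switching", "as_printed")


@dataclass
class TemperatureTrace:
    """Measured or synthetic tumor temperature time course (deg C)."""

    times: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.times.shape != self.T.shape or self.times.ndim != 1:
            raise InputError("times and T must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("temperature times must be strictly increasing")

    def at(self, t):
        """Linear interpolation; end values held outside the trace."""
        return np.interp(t, self.times, self.T)


@dataclass
class Trajectory:
    """Simulation output on the requested sampling grid.

    ``c_p_T_mean`` is the spatial mean of the free tumor-plasma profile,
    the quantity comparable to the intravascular imaging signal;
    ``c_dds_T_mean`` the same for encapsulated drug.  ``eliminated`` is
    the cumulative eliminated amount (mass units).
    """

    t: np.ndarray
    c_e_T: np.ndarray
    c_p_S: np.ndarray
    c_t_S: np.ndarray
    c_p_DDS_S: np.ndarray
    eliminated: np.ndarray
    c_p_T_mean: np.ndarray
    c_dds_T_mean: np.ndarray
    c_p_T_out: np.ndarray
    metadata: dict = field(default_factory=dict)

    def mass_ledger(self, bundle: ParameterBundle,
                    include_vascular: bool = False) -> np.ndarray:
        """Total accounted mass at each output time.

        Free systemic drug is carried on the initial-distribution-volume
        basis ``V_D`` (the bolus initial condition ``c_p_S = ID/V_D``
        makes the initial free mass exactly the injected dose).  The
        quasi-steady tumor vascular content (order ``V_p_T``, ~1/700 of
        the systemic pool) holds no storage in the model; pass
        ``include_vascular=True`` to add it as a diagnostic.
        """
        v_e = bundle.tumor.v_e_av
        total = (
            self.c_e_T * v_e * bundle.geometry.VT
            + (self.c_p_S + self.c_t_S) * bundle.pk.V_D
            + self.c_p_DDS_S * bundle.pk.V_p_S
            + self.eliminated
        )
        if include_vascular:
            total = total + (self.c_p_T_mean + self.c_dds_T_mean) * bundle.geometry.V_p_T
        return total


def _release_rate_fn(release, temperature: Optional[TemperatureTrace]):
    """Precompute the fractional release rate 1/t_rel as a function of t."""
    if release is None:
        return lambda t: 0.0
    model = release if isinstance(release, ReleaseRateModel) else ReleaseRateModel(release)
    if temperature is None:
        raise InputError("a temperature trace is required when a release table is given")
    times = temperature.times
    rates = model.rate(temperature.T)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    return lambda t: float(np.interp(t, times, rates))


def simulate_ivdds(
    bundle: ParameterBundle,
    release: Union[ReleaseTable, ReleaseRateModel],
    temperature: TemperatureTrace,
    dose: DoseSpec,
    duration: float,
    output_dt: float = 1.0,
    *,
    f_distr_mode: str = "mass",
    use_v_e_av: bool = True,
    recirculation: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    max_step: float = 10.0,
) -> Trajectory:
    """Simulate triggered intravascular delivery of an encapsulated dose.

    The encapsulated drug starts uniformly distributed in systemic
    plasma (``c_dds_S(0) = ID / V_p_S``); all free-drug pools start at
    zero.  ``recirculation=False`` freezes the systemic pools (constant
    encapsulated supply, zero inlet free concentration), which isolates
    the single-pass tumor dynamics underlying the plateau analysis.
    """
    if dose.form != "encapsulated":
        raise InvalidParameterError("simulate_ivdds requires an encapsulated dose")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if f_distr_mode not in F_DISTR_MODES:
        raise InvalidParameterError(f"f_distr_mode must be one of {F_DISTR_MODES}")
    if temperature.times[-1] < duration:
        log.warning(
            "temperature trace ends at %.1f s before duration %.1f s; "
            "holding the last value", temperature.times[-1], duration)

    tu, pk, geo = bundle.tumor, bundle.pk, bundle.geometry
    k = tu.PS / tu.F_p
    TT = tu.TT
    Q = geo.V_p_T * tu.F_p / tu.v_p
    v_e_use = tu.v_e_av if use_v_e_av else (tu.v_e if tu.v_e is not None else tu.v_e_av)
    rate_fn = _release_rate_fn(release, temperature)
    c_dds0 = dose.ID / pk.V_p_S
    clipped = [False]

    def rhs(t, y):
        c_e, c_pS, c_tS, c_ddsS, _ = y
        if c_e < 0 or c_pS < 0 or c_tS < 0 or c_ddsS < 0:
            clipped[0] = True
            c_e, c_pS = max(c_e, 0.0), max(c_pS, 0.0)
            c_tS, c_ddsS = max(c_tS, 0.0), max(c_ddsS, 0.0)
        r = TT * rate_fn(t)
        c_in = 0.0 if not recirculation else c_pS
        ep = solve_endpoint(GradientInputs(
            k=k, r=r, c_e_T=c_e, c_p_in=c_in,
            c_dds_sys=c_ddsS, c_dds_in=c_ddsS))
        d_ce = (tu.F_p / v_e_use) * ep.c_extr
        if recirculation:
            dc = ep.c_p_out - c_pS
            if f_distr_mode == "mass":
                exch = Q * dc / pk.V_D
            elif f_distr_mode == "switching":
                exch = Q * dc / (pk.V_D if dc > 0.0 else pk.V_p_S)
            else:  # as_printed
                f_distr = geo.V_p_T / pk.V_D if dc > 0.0 else 1.0
                exch = (Q / pk.V_p_S) * dc * f_distr
            d_cpS = exch - (pk.k_e + pk.k_p) * c_pS + pk.k_t * c_tS
            d_ctS = pk.k_p * c_pS - pk.k_t * c_tS
            d_cdds = (Q / pk.V_p_S) * (ep.c_dds_out - c_ddsS)
            d_elim = pk.k_e * c_pS * pk.V_D
        else:
            d_cpS = d_ctS = d_cdds = d_elim = 0.0
        return (d_ce, d_cpS, d_ctS, d_cdds, d_elim)

    y0 = [0.0, 0.0, 0.0, c_dds0, 0.0]
    t_out = np.arange(0.0, duration + 0.5 * output_dt, output_dt)
    t_out[-1] = min(t_out[-1], duration)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="RK45", t_eval=t_out,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    if clipped[0]:
        log.warning("negative concentrations from solver overshoot were clipped to 0")

    c_e, c_pS, c_tS, c_dds, elim = np.maximum(sol.y, 0.0)
    elim = sol.y[4]
    mean_p = np.empty_like(sol.t)
    mean_d = np.empty_like(sol.t)
    out_p = np.empty_like(sol.t)
    for i, (t, ce_i, cp_i, cd_i) in enumerate(zip(sol.t, c_e, c_pS, c_dds)):
        r = TT * rate_fn(t)
        ep = solve_endpoint(GradientInputs(
            k=k, r=r, c_e_T=ce_i,
            c_p_in=(cp_i if recirculation else 0.0),
            c_dds_sys=cd_i, c_dds_in=cd_i))
        mean_p[i], mean_d[i], out_p[i] = ep.mean_c_p, ep.mean_c_dds, ep.c_p_out

    return Trajectory(
        t=sol.t, c_e_T=c_e, c_p_S=c_pS, c_t_S=c_tS, c_p_DDS_S=c_dds,
        eliminated=elim, c_p_T_mean=mean_p, c_dds_T_mean=mean_d, c_p_T_out=out_p,
        metadata={
            "mode": "ivdds", "ID": dose.ID, "f_distr_mode": f_distr_mode,
            "recirculation": recirculation, "rtol": rtol, "atol": atol,
            "use_v_e_av": use_v_e_av,
        })


def simulate_free(
    bundle: ParameterBundle,
    dose: DoseSpec,
    duration: float,
    output_dt: float = 1.0,
    *,
    f_distr_mode: str = "mass",
    use_v_e_av: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    max_step: float = 10.0,
) -> Trajectory:
    """Simulate a bolus of unencapsulated drug.

    Bolus at ``t = 0`` with immediate distribution in the initial
    distribution volume: ``c_p_S(0) = ID / V_D``.  Tumor uptake follows
    the gradient model with zero release.
    """
    if dose.form != "free":
        raise InvalidParameterError("simulate_free requires a free dose")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if f_distr_mode not in F_DISTR_MODES:
        raise InvalidParameterError(f"f_distr_mode must be one of {F_DISTR_MODES}")

    tu, pk, geo = bundle.tumor, bundle.pk, bundle.geometry
    k = tu.PS / tu.F_p
    Q = geo.V_p_T * tu.F_p / tu.v_p
    v_e_use = tu.v_e_av if use_v_e_av else (tu.v_e if tu.v_e is not None else tu.v_e_av)

    def rhs(t, y):
        c_e, c_pS, c_tS, _ = y
        c_e, c_pS, c_tS = max(c_e, 0.0), max(c_pS, 0.0), max(c_tS, 0.0)
        ep = solve_endpoint(GradientInputs(k=k, r=0.0, c_e_T=c_e, c_p_in=c_pS))
        d_ce = (tu.F_p / v_e_use) * ep.c_extr
        dc = ep.c_p_out - c_pS
        if f_distr_mode == "mass":
            exch = Q * dc / pk.V_D
        elif f_distr_mode == "switching":
            exch = Q * dc / (pk.V_D if dc > 0.0 else pk.V_p_S)
        else:
            f_distr = geo.V_p_T / pk.V_D if dc > 0.0 else 1.0
            exch = (Q / pk.V_p_S) * dc * f_distr
        d_cpS = exch - (pk.k_e + pk.k_p) * c_pS + pk.k_t * c_tS
        d_ctS = pk.k_p * c_pS - pk.k_t * c_tS
        d_elim = pk.k_e * c_pS * pk.V_D
        return (d_ce, d_cpS, d_ctS, d_elim)

    y0 = [0.0, dose.ID / pk.V_D, 0.0, 0.0]
    t_out = np.arange(0.0, duration + 0.5 * output_dt, output_dt)
    t_out[-1] = min(t_out[-1], duration)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="RK45", t_eval=t_out,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    c_e, c_pS, c_tS = np.maximum(sol.y[:3], 0.0)
    elim = sol.y[3]
    mean_p = np.empty_like(sol.t)
    out_p = np.empty_like(sol.t)
    for i, (ce_i, cp_i) in enumerate(zip(c_e, c_pS)):
        ep = solve_endpoint(GradientInputs(k=k, r=0.0, c_e_T=ce_i, c_p_in=cp_i))
        mean_p[i], out_p[i] = ep.mean_c_p, ep.c_p_out

    return Trajectory(
        t=sol.t, c_e_T=c_e, c_p_S=c_pS, c_t_S=c_tS,
        c_p_DDS_S=np.zeros_like(sol.t), eliminated=elim,
        c_p_T_mean=mean_p, c_dds_T_mean=np.zeros_like(sol.t), c_p_T_out=out_p,
        metadata={
            "mode": "free", "ID": dose.ID, "f_distr_mode": f_distr_mode,
            "rtol": rtol, "atol": atol, "use_v_e_av": use_v_e_av,
        })


def mean_absolute_error(
    sim: Trajectory,
    obs_times,
    obs_values,
    horizon: float,
) -> tuple[float, float]:
    """Time-averaged absolute error between simulated and observed EES traces.

    ``MAE = (1/T) \\int_0^T |c_obs(t) - c_sim(t)| dt`` evaluated by the
    trapezoid rule on the union of the two time grids within [0, T],
    with linear interpolation of both series; the normalized MAE divides
    by the maximum observed concentration.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    if obs_times.size == 0:
        raise InputError("empty observation series")
    grid = np.union1d(sim.t, obs_times)
    grid = grid[(grid >= 0.0) & (grid <= horizon)]
    if grid.size < 2:
        raise InputError("observations do not overlap the horizon [0, T]")
    sim_i = np.interp(grid, sim.t, sim.c_e_T)
    obs_i = np.interp(grid, obs_times, obs_values)
    T = grid[-1] - grid[0]
    mae = np.trapezoid(np.abs(obs_i - sim_i), grid) / T
    peak = float(np.max(obs_values))
    nmae = mae / peak if peak > 0 else math.inf
    return float(mae), float(nmae)
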