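"""Computational studies on top of the delivery model.

Three analyses:

* a parametric map of the plateau concentration over the release index
  (RI) and permeability index (PI), via the closed-form fixed point or
  full time integration at a constant trigger;
* Monte Carlo uncertainty propagation with moment-matched log-normal
  parameter distributions;
* variance-based global sensitivity analysis (Sobol first-order and
  total indices) of an RMSE objective, using a Saltelli sample design
  built from Latin hypercube draws and Jansen estimators.

Derived parameters (F_p, V_p_T, EF) are always recomputed from the
sampled primitives, never sampled independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .compartment import TemperatureTrace, Trajectory, simulate_free, simulate_ivdds
from .errors import ConfigurationError, InputError, InvalidParameterError
from .gradient import plateau_concentration
from .params import DoseSpec, ParameterBundle, validate_params
from .release import ReleaseTable

#: Default relative standard deviation assumed for parameters without an
#: experimental uncertainty estimate (e.g. release time, tumor volume).
DEFAULT_SD_FRACTION = 0.10

#: Primitive (non-derived) parameters entering the sampling analyses.
#: Derived quantities (F_p, V_p_T, EF) are recomputed per draw, and the
#: systemic plasma volume V_p_S is held fixed because it is computed
#: from the measured body weight rather than estimated with uncertainty.
PRIMITIVE_PARAMS = ("v_p", "v_e_av", "TT", "PS",
                    "V_D", "k_p", "k_t", "k_e", "VT")


# ---------------------------------------------------------------------------
# log-normal sampling, moment matched on arithmetic mean / SD


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise InvalidParameterError("log-normal mean must be > 0")
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def lognormal_ppf(u, mean: float, sd: float):
    """Inverse CDF of the moment-matched log-normal (for LHS transforms)."""
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    mu, sigma = lognormal_params(mean, sd)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def sample_lognormal(rng: np.random.Generator, mean: float, sd: float, size):
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def _param_means_sds(bundle: ParameterBundle, include_t_rel: bool,
                     t_rel_mean: float = 1.0) -> tuple[list, np.ndarray, np.ndarray]:
    """Means and SDs of the sampled primitives, with the 10% default.

    ``t_rel`` enters as a dimensionless scale factor (mean 1) applied to
    the whole release table, preserving its temperature dependence.
    """
    sections = {**{k: (bundle.tumor, getattr(bundle.tumor, k))
                   for k in ("v_p", "v_e_av", "TT", "PS")},
                **{k: (bundle.pk, getattr(bundle.pk, k))
                   for k in ("V_D", "k_p", "k_t", "k_e")},
                "VT": (bundle.geometry, bundle.geometry.VT)}
    names, means, sds = [], [], []
    for name in PRIMITIVE_PARAMS:
        obj, mean = sections[name]
        sd = dict(obj.sd).get(name, DEFAULT_SD_FRACTION * mean)
        names.append(name)
        means.append(mean)
        sds.append(sd)
    if include_t_rel:
        names.append("t_rel")
        means.append(t_rel_mean)
        sds.append(DEFAULT_SD_FRACTION * t_rel_mean)
    return names, np.asarray(means), np.asarray(sds)


def _bundle_from_sample(bundle: ParameterBundle, names, values) -> tuple[ParameterBundle, float]:
    """Rebuild a validated bundle from sampled primitives.

    Fractions are capped just below 1 (the log-normal has unbounded
    support); derived fields are recomputed by validation.  Returns the
    bundle and the release-time scale factor (1 when not sampled).
    """
    d = dict(zip(names, values))
    tumor = replace(bundle.tumor,
                    v_p=min(d["v_p"], 0.999), v_e_av=min(d["v_e_av"], 0.999),
                    TT=d["TT"], PS=d["PS"], F_p=None, v_v=None, v_e=None,
                    k_av=None, sd={})
    pk = replace(bundle.pk, V_D=d["V_D"],
                 k_p=d["k_p"], k_t=d["k_t"], k_e=d["k_e"], sd={})
    geo = replace(bundle.geometry, VT=d["VT"], V_p_T=None, sd={})
    return validate_params(tumor, pk, geo), d.get("t_rel", 1.0)


def _scaled_table(release: ReleaseTable, factor: float) -> ReleaseTable:
    return ReleaseTable(temperatures=release.temperatures,
                        t_rel=release.t_rel * factor, label=release.label)


# ---------------------------------------------------------------------------
# parametric map


@dataclass
class ParametricMap:
    """Plateau-concentration map over the two delivery indices.

    ``plateau[i, j]`` is the plateau fraction at ``PI_grid[i]``,
    ``RI_grid[j]``.  ``annotations`` holds (label, RI, PI) experimental
    anchor points.
    """

    RI_grid: np.ndarray
    PI_grid: np.ndarray
    plateau: np.ndarray
    method: str
    annotations: list = field(default_factory=list)


def plateau_rate_constant(bundle: ParameterBundle, PI: float) -> float:
    """Exponential approach rate of the EES toward the plateau (1/s).

    From the gradient closed form, ``dc_e/dt`` is proportional to
    ``(C* - c_e)`` with rate ``F_p (1 - e^{-k}) / v_e_av``.
    """
    return bundle.tumor.F_p * (-math.expm1(-PI)) / bundle.tumor.v_e_av


def plateau_from_simulation(
    RI: float,
    PI: float,
    bundle: ParameterBundle,
    *,
    recirculation: bool = True,
    dose_ID: float = 1.0,
    duration: Optional[float] = None,
    rtol: float = 1e-8,
) -> float:
    """Plateau fraction from full time integration at a constant trigger.

    ``PS`` and the release time are adjusted to hit the target indices
    while every other parameter keeps its value; the trigger is held
    constant so the release rate is fixed at ``1/t_rel``.  The plateau
    is the maximum of ``c_e_T(t) / c_p_DDS_S(t)``, the EES concentration
    as a fraction of the instantaneous maximum possible (the systemic
    encapsulated plasma concentration).
    """
    b = bundle.copy()
    b.tumor.PS = PI * b.tumor.F_p
    b = validate_params(b.tumor, b.pk, b.geometry)
    t_rel = RI * b.tumor.TT
    table = ReleaseTable(temperatures=np.array([42.0]), t_rel=np.array([t_rel]))
    if duration is None:
        lam = plateau_rate_constant(b, PI)
        duration = min(max(10.0 / lam, 300.0), 14400.0)
    temp = TemperatureTrace(times=np.array([0.0, duration]),
                            T=np.array([42.0, 42.0]))
    traj = simulate_ivdds(b, table, temp, DoseSpec(ID=dose_ID, form="encapsulated"),
                          duration, output_dt=duration / 400.0,
                          recirculation=recirculation, rtol=rtol,
                          max_step=duration / 50.0)
    frac = traj.c_e_T / np.maximum(traj.c_p_DDS_S, 1e-300)
    return float(np.max(frac))


def parametric_map(
    RI_grid,
    PI_grid,
    method: str = "fixed_point",
    bundle: Optional[ParameterBundle] = None,
    annotations: Sequence[tuple] = (),
    **sim_kwargs,
) -> ParametricMap:
    """Plateau concentration over an (RI, PI) grid.

    The fixed-point path evaluates the closed-form plateau and covers a
    ~1200-cell map in milliseconds; the full-simulation path integrates
    the compartment model at a constant trigger per cell and needs a
    validated parameter bundle.
    """
    RI_grid = np.asarray(RI_grid, dtype=float)
    PI_grid = np.asarray(PI_grid, dtype=float)
    if np.any(RI_grid <= 0) or np.any(PI_grid <= 0):
        raise InvalidParameterError("index grids must be positive")
    plateau = np.empty((PI_grid.size, RI_grid.size))
    if method == "fixed_point":
        for i, pi in enumerate(PI_grid):
            for j, ri in enumerate(RI_grid):
                plateau[i, j] = plateau_concentration(ri, pi)
    elif method == "full_simulation":
        if bundle is None:
            raise ConfigurationError("full_simulation requires a parameter bundle")
        for i, pi in enumerate(PI_grid):
            for j, ri in enumerate(RI_grid):
                plateau[i, j] = plateau_from_simulation(ri, pi, bundle, **sim_kwargs)
    else:
        raise InvalidParameterError("method must be 'fixed_point' or 'full_simulation'")
    return ParametricMap(RI_grid=RI_grid, PI_grid=PI_grid, plateau=plateau,
                         method=method, annotations=list(annotations))


# ---------------------------------------------------------------------------
# scenario runner shared by the sampling analyses


def _run_scenario(
    bundle: ParameterBundle,
    scenario: str,
    dose: DoseSpec,
    duration: float,
    output_dt: float,
    temperature: Optional[TemperatureTrace],
    release: Optional[ReleaseTable],
    t_rel_factor: float = 1.0,
    rtol: float = 1e-6,
) -> Trajectory:
    if scenario == "free":
        return simulate_free(bundle, dose, duration, output_dt, rtol=rtol)
    if scenario == "ivdds":
        if temperature is None or release is None:
            raise ConfigurationError(
                "ivdds scenario requires a temperature trace and release table")
        table = release if t_rel_factor == 1.0 else _scaled_table(release, t_rel_factor)
        return simulate_ivdds(bundle, table, temperature, dose, duration,
                              output_dt, rtol=rtol)
    raise InvalidParameterError("scenario must be 'free' or 'ivdds'")


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty propagation


@dataclass
class UncertaintyResult:
    """Per-time-point mean and SD of the model outputs over parameter draws."""

    t: np.ndarray
    mean_c_p: np.ndarray   # capillary-mean tumor plasma concentration
    sd_c_p: np.ndarray
    mean_c_e: np.ndarray   # tumor EES concentration
    sd_c_e: np.ndarray
    n_samples: int
    seed: int


def monte_carlo_uncertainty(
    bundle: ParameterBundle,
    scenario: str,
    dose: DoseSpec,
    n: int = 1000,
    seed: int = 0,
    duration: float = 1200.0,
    output_dt: float = 10.0,
    temperature: Optional[TemperatureTrace] = None,
    release: Optional[ReleaseTable] = None,
    rtol: float = 1e-6,
) -> UncertaintyResult:
    """Monte Carlo propagation of parameter uncertainty.

    Each primitive parameter is drawn from a log-normal matched to its
    stated mean and SD (missing SDs default to 10% of the mean);
    derived parameters are recomputed per draw.  Returns per-time mean
    and SD of the capillary-mean tumor plasma concentration and the EES
    concentration.  Bit-reproducible for a fixed seed.
    """
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    names, means, sds = _param_means_sds(bundle, include_t_rel=(scenario == "ivdds"))
    rng = np.random.default_rng(seed)
    draws = np.column_stack([
        sample_lognormal(rng, m, s, n) for m, s in zip(means, sds)])

    c_p_runs = []
    c_e_runs = []
    t_grid = None
    for row in draws:
        b, factor = _bundle_from_sample(bundle, names, row)
        traj = _run_scenario(b, scenario, dose, duration, output_dt,
                             temperature, release, factor, rtol)
        t_grid = traj.t
        c_p_runs.append(traj.c_p_T_mean)
        c_e_runs.append(traj.c_e_T)
    c_p = np.vstack(c_p_runs)
    c_e = np.vstack(c_e_runs)
    return UncertaintyResult(
        t=t_grid,
        mean_c_p=c_p.mean(axis=0), sd_c_p=c_p.std(axis=0, ddof=1),
        mean_c_e=c_e.mean(axis=0), sd_c_e=c_e.std(axis=0, ddof=1),
        n_samples=n, seed=seed)


# ---------------------------------------------------------------------------
# Sobol sensitivity (Saltelli design, Jansen estimators)


@dataclass
class SensitivityResult:
    """First-order and total Sobol indices of the RMSE objective."""

    names: list
    S1: np.ndarray
    ST: np.ndarray
    n_base: int
    n_runs: int
    seed: int
    variance: float


def rmse_objective(sim: Union[Trajectory, tuple], ref: Union[Trajectory, tuple],
                   T: float) -> float:
    """Root-mean-square discrepancy of the EES concentration over [0, T].

    ``Err = sqrt((1/T) \\int_0^T (c_e - c_e_ref)^2 dt)`` by the trapezoid
    rule on the union grid, with linear interpolation of both series.
    """
    st, sv = (sim.t, sim.c_e_T) if isinstance(sim, Trajectory) else sim
    rt, rv = (ref.t, ref.c_e_T) if isinstance(ref, Trajectory) else ref
    st, sv = np.asarray(st, float), np.asarray(sv, float)
    rt, rv = np.asarray(rt, float), np.asarray(rv, float)
    grid = np.union1d(st, rt)
    grid = grid[(grid >= 0.0) & (grid <= T)]
    if grid.size < 2:
        raise InputError("series do not overlap the horizon [0, T]")
    diff = np.interp(grid, st, sv) - np.interp(grid, rt, rv)
    span = grid[-1] - grid[0]
    return float(math.sqrt(np.trapezoid(diff * diff, grid) / span))


def sobol_sensitivity(
    bundle: ParameterBundle,
    scenario: str,
    dose: DoseSpec,
    n_base: int = 512,
    seed: int = 0,
    duration: float = 1200.0,
    output_dt: float = 30.0,
    temperature: Optional[TemperatureTrace] = None,
    release: Optional[ReleaseTable] = None,
    rtol: float = 1e-6,
    objective=None,
) -> SensitivityResult:
    """Variance-based global sensitivity of the delivery outcome.

    Sample matrices A and B come from a Latin hypercube in the unit
    cube, transformed through the moment-matched log-normal inverse
    CDFs; the Saltelli design evaluates the model on A, B and the k
    column-swapped matrices AB_i, for ``n_base * (k + 2)`` runs total.
    Jansen's estimators give the first-order and total indices of the
    objective — by default the RMSE (over ``duration``) of the EES
    concentration against the all-means reference run.

    ``objective`` may be a callable ``f(values: dict) -> float`` to
    analyze an arbitrary function of the parameters instead (used for
    closed-form verification).
    """
    names, means, sds = _param_means_sds(bundle, include_t_rel=(scenario == "ivdds"))
    k = len(names)
    sampler = qmc.LatinHypercube(d=2 * k, seed=seed)
    u = sampler.random(n=n_base)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    A = np.column_stack([lognormal_ppf(u[:, i], means[i], sds[i])
                         for i in range(k)])
    B = np.column_stack([lognormal_ppf(u[:, k + i], means[i], sds[i])
                         for i in range(k)])

    if objective is None:
        ref = _run_scenario(bundle, scenario, dose, duration, output_dt,
                            temperature, release, 1.0, rtol)

        def objective(values: dict) -> float:
            b, factor = _bundle_from_sample(bundle, names, [values[n] for n in names])
            traj = _run_scenario(b, scenario, dose, duration, output_dt,
                                 temperature, release, factor, rtol)
            return rmse_objective(traj, ref, duration)

    def evaluate(matrix: np.ndarray) -> np.ndarray:
        return np.array([objective(dict(zip(names, row))) for row in matrix])

    fA = evaluate(A)
    fB = evaluate(B)
    fAB = np.empty((k, n_base))
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = evaluate(ABi)

    allf = np.concatenate([fA, fB])
    V = float(np.var(allf, ddof=1))
    if V <= 0:
        raise ConfigurationError("objective has zero variance; indices undefined")
    S1 = np.array([1.0 - np.mean((fB - fAB[i]) ** 2) / (2.0 * V) for i in range(k)])
    ST = np.array([np.mean((fA - fAB[i]) ** 2) / (2.0 * V) for i in range(k)])
    return SensitivityResult(names=list(names), S1=S1, ST=ST, n_base=n_base,
                             n_runs=n_base * (k + 2), seed=seed, variance=V)


# ---------------------------------------------------------------------------
# replication statistic


def replication_ci_halfwidth(n: int, level: float = 0.90) -> float:
    """Normal-theory CI half-width for a mean of n replicates, in SD units.

    ``z_{(1+level)/2} / sqrt(n)`` — e.g. three replicates give a 90%
    confidence interval of +/- 0.95 standard deviations.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    return float(stats.norm.ppf(0.5 * (1.0 + level)) / math.sqrt(n))
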