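"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is the measurable inverse of the corresponding estimator
at zero noise, so round-trip identities anchor the estimation tests.
The noise model is multiplicative log-normal (signal-proportional
detector noise), moment-matched to mean 1, plus an optional additive
floor.  Ground-truth parameters are embedded in trace metadata so tests
never re-derive them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .compartment import TemperatureTrace, Trajectory, simulate_free, simulate_ivdds
from .errors import InvalidParameterError
from .estimation import (
    Biexponential,
    BloodSampleSeries,
    CalibrationSpec,
    FluorescenceTrace,
    biexponential_from_rate_constants,
)
from .params import DoseSpec, ParameterBundle, SystemicPK
from .release import InVitroReleaseTrace, ReleaseTable


@dataclass
class NoiseSpec:
    """Measurement-noise description with a single seed.

    ``multiplicative_sd`` is the coefficient of variation of a
    log-normal factor with mean 1; ``additive_sd`` a zero-mean Gaussian
    floor in the trace's own units.
    """

    multiplicative_sd: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.multiplicative_sd > 0:
            sigma2 = math.log1p(self.multiplicative_sd ** 2)
            factors = rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2),
                                    size=out.shape)
            out = out * factors
        if self.additive_sd > 0:
            out = out + rng.normal(0.0, self.additive_sd, size=out.shape)
        return out


def gen_temperature_trace(
    ramp_s: float = 180.0,
    plateau_C: float = 42.0,
    hold_s: float = 420.0,
    baseline_C: float = 37.0,
    cool_tau_s: float = 60.0,
    dt: float = 2.0,
) -> TemperatureTrace:
    """Piecewise hyperthermia temperature course.

    Exponential approach from baseline to the plateau over roughly
    ``ramp_s`` (time constant ``ramp_s/3``, ~95% at the ramp end), a
    hold, and exponential cool-down back to baseline with time constant
    ``cool_tau_s``.  Defaults mimic a ~10 min 42 degC exposure sampled
    every 2 s.
    """
    if min(ramp_s, hold_s, cool_tau_s, dt) <= 0:
        raise InvalidParameterError("all durations must be > 0")
    t_off = ramp_s + hold_s
    duration = t_off + 5.0 * cool_tau_s
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    tau_ramp = ramp_s / 3.0
    T = np.where(
        times <= t_off,
        plateau_C + (baseline_C - plateau_C) * np.exp(-times / tau_ramp),
        np.nan)
    T_off = plateau_C + (baseline_C - plateau_C) * math.exp(-t_off / tau_ramp)
    cooling = times > t_off
    T[cooling] = baseline_C + (T_off - baseline_C) * np.exp(
        -(times[cooling] - t_off) / cool_tau_s)
    return TemperatureTrace(times=times, T=T)


def gen_fluorescence_traces(
    bundle: ParameterBundle,
    dose: DoseSpec,
    scenario: str,
    calib: CalibrationSpec,
    noise: NoiseSpec,
    frame_dt: float = 4.0,
    duration: float = 1200.0,
    temperature: Optional[TemperatureTrace] = None,
    release: Optional[ReleaseTable] = None,
    rtol: float = 1e-8,
) -> FluorescenceTrace:
    """Forward-simulate and convert to raw intensity traces.

    ``free``: intensities are the inverse of the free-mode calibration,
    ``I_v = c_p (1-Hct)/scale``, ``I_e = c_e k_av/scale`` with ``c_p``
    the capillary-mean tumor plasma concentration.  ``ivdds``: the
    intravascular channel mixes quenched encapsulated dye (brightness
    reduced by the dequench factor) and released free dye.
    """
    if scenario == "free":
        traj = simulate_free(bundle, dose, duration, output_dt=frame_dt, rtol=rtol)
        I_v = traj.c_p_T_mean * (1.0 - calib.Hct_mv) / calib.scale
        I_e = traj.c_e_T * calib.k_av / calib.scale
    elif scenario == "ivdds":
        if temperature is None or release is None:
            raise InvalidParameterError(
                "ivdds scenario requires a temperature trace and a release table")
        traj = simulate_ivdds(bundle, release, temperature, dose, duration,
                              output_dt=frame_dt, rtol=rtol)
        D = calib.dequench_factor
        I_v = (1.0 - calib.Hct_mv) * (traj.c_dds_T_mean / D
                                      + traj.c_p_T_mean) / calib.scale
        I_e = traj.c_e_T * calib.k_av / calib.scale
    else:
        raise InvalidParameterError("scenario must be 'free' or 'ivdds'")

    rng = noise.rng()
    meta = {
        "scenario": scenario,
        "truth": {
            "PS": bundle.tumor.PS, "k_av": calib.k_av,
            "v_e_av": bundle.tumor.v_e_av, "TT": bundle.tumor.TT,
            "Hct_mv": calib.Hct_mv, "scale": calib.scale,
            "ID": dose.ID,
        },
        "noise": {"multiplicative_sd": noise.multiplicative_sd,
                  "additive_sd": noise.additive_sd, "seed": noise.seed},
    }
    return FluorescenceTrace(
        times=traj.t,
        I_v=noise.apply(I_v, rng),
        I_e=noise.apply(I_e, rng),
        metadata=meta,
    )


def gen_blood_samples(
    pk: Union[SystemicPK, Sequence[float]],
    ID: float,
    times: Sequence[float],
    noise: NoiseSpec,
    V_D: Optional[float] = None,
) -> BloodSampleSeries:
    """Closed-form two-compartment plasma concentrations at sample times.

    ``pk`` is either a :class:`SystemicPK` (``V_D`` taken from it) or a
    ``(k_t, k_p, k_e)`` triple in the :func:`ivdds.estimation.rate_constants`
    convention (``k_t`` plasma->tissue, ``k_p`` tissue->plasma), in which
    case ``V_D`` must be given.  Multiplicative log-normal noise is applied.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("times must be non-empty")
    if isinstance(pk, SystemicPK):
        k_t, k_p, k_e, V_D = pk.k_t, pk.k_p, pk.k_e, pk.V_D
    else:
        k_t, k_p, k_e = pk
        if V_D is None:
            raise InvalidParameterError("V_D required with a rate-constant triple")
    fit = biexponential_from_rate_constants(k_t, k_p, k_e, C0=ID / V_D)
    conc = fit(times)
    rng = noise.rng()
    return BloodSampleSeries(times=times, concentration=noise.apply(conc, rng),
                             dose=ID)


def gen_release_trace(
    t_rel: float,
    duration: float = 20.0,
    dt: float = 1.0,
    Fl_b: float = 100.0,
    Fl_m: float = 1100.0,
    noise: NoiseSpec = NoiseSpec(),
    temperature: Optional[float] = None,
) -> InVitroReleaseTrace:
    """Zero-order in-vitro release trace in raw fluorescence units.

    Percent release ramps linearly, ``min(100, 100 t / t_rel)``, and is
    mapped back through the percent-release inverse to raw fluorescence
    between background ``Fl_b`` and complete-release ``Fl_m``.
    """
    if t_rel <= 0:
        raise InvalidParameterError("t_rel must be > 0")
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    pct = np.minimum(100.0, 100.0 * times / t_rel)
    fl = Fl_b + pct / 100.0 * (Fl_m - Fl_b)
    rng = noise.rng()
    return InVitroReleaseTrace(times=times, Fl_n=noise.apply(fl, rng),
                               Fl_b=Fl_b, Fl_m=Fl_m, temperature=temperature)
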