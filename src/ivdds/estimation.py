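"""Parameter quantification from imaging, blood-sample and assay data.

The pipeline mirrors how the transport parameters are measured in vivo:

* ``fit_permeability`` — fits the intensity-space two-compartment uptake
  equation ``dI_e/dt = (PS/v_e) (I_v/(1-Hct_mv) - I_e/k_av)`` to the
  intra-/extravascular fluorescence time courses, returning the
  permeability-surface-area product ``PS`` and the available
  extravascular volume fraction ``k_av``.
* ``estimate_transit_time`` — recovers the microvascular transit time
  from the early intravascular signal after a rapid bolus, modeled as
  the step response of an exponential-washout residue:
  ``I_v(t) = A (1 - exp(-(t - t0)/TT))`` for ``t >= t0``.
* ``fit_biexponential`` / ``rate_constants`` — classical two-compartment
  pharmacokinetics from serial blood samples,
  ``C(t) = C0 (a e^{-l1 t} + (1-a) e^{-l2 t})``, mapped to the three
  rate constants via the standard macro-to-micro conversion.
* ``fluorescence_to_concentration`` — converts calibrated fluorescence
  to absolute concentration, including the dequenching of encapsulated
  dye on release (fluorescence increases ``dequench_factor``-fold,
  default 30.2, between the quenched encapsulated state and free dye).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import CalibrationError, EstimationError, InputError, InvalidParameterError
from .params import DEFAULT_HCT_MV

#: Fluorescence enhancement factor between quenched (encapsulated) and
#: free dye, measured in vitro after complete release.
DEFAULT_DEQUENCH_FACTOR = 30.2


@dataclass
class FluorescenceTrace:
    """Mean intra- and extravascular fluorescence intensity over time."""

    times: np.ndarray          # s, strictly increasing
    I_v: np.ndarray            # a.u.
    I_e: np.ndarray            # a.u.
    background_subtracted: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.I_v = np.asarray(self.I_v, dtype=float)
        self.I_e = np.asarray(self.I_e, dtype=float)
        if not (self.times.shape == self.I_v.shape == self.I_e.shape):
            raise InputError("times, I_v, I_e must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.I_v)) and np.all(np.isfinite(self.I_e))):
            raise InputError("intensities must be finite")


@dataclass
class BloodSampleSeries:
    """Plasma concentrations from serial blood sampling after a bolus."""

    times: np.ndarray          # s
    concentration: np.ndarray  # amount/mL
    dose: Optional[float] = None   # injected dose, amount

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape:
            raise InputError("times and concentration must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.times.size < 3:
            raise InputError("need >= 3 blood samples")


@dataclass
class Biexponential:
    """Bi-exponential plasma decay C(t) = C0 (a e^{-l1 t} + (1-a) e^{-l2 t}).

    Convention: ``lambda1 >= lambda2`` (fast phase first).
    """

    C0: float
    alpha: float
    lambda1: float
    lambda2: float

    def __post_init__(self):
        if self.lambda1 < self.lambda2:
            self.lambda1, self.lambda2 = self.lambda2, self.lambda1
            self.alpha = 1.0 - self.alpha
        # lambda2 == 0 is the degenerate no-slow-phase boundary (e.g. a
        # two-compartment system without tissue exchange)
        if self.lambda1 <= 0 or self.lambda2 < 0:
            raise InvalidParameterError("decay rates must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.C0 * (self.alpha * np.exp(-self.lambda1 * t)
                          + (1.0 - self.alpha) * np.exp(-self.lambda2 * t))


@dataclass
class CalibrationSpec:
    """Intensity-to-concentration calibration for intravital imaging.

    ``scale`` converts intensity of free (unquenched) dye to
    concentration at unit available volume fraction (amount/mL per a.u.).
    """

    scale: float
    dequench_factor: float = DEFAULT_DEQUENCH_FACTOR
    Hct_mv: float = DEFAULT_HCT_MV
    k_av: float = 1.0

    def __post_init__(self):
        if not self.scale > 0:
            raise CalibrationError("calibration scale must be > 0")
        if not self.dequench_factor > 1:
            raise CalibrationError("dequench factor must be > 1")


# ---------------------------------------------------------------------------
# permeability / available-fraction fit


def _integrate_uptake(times, I_v, a: float, b: float, I_e0: float) -> np.ndarray:
    """Exact solution of dI_e/dt = a I_v(t) - b I_e with piecewise-linear I_v.

    On each sampling interval the forcing is linear, so the linear ODE
    has an exact exponential-integrator update; no step-size error enters
    the fit.
    """
    n = times.size
    out = np.empty(n)
    out[0] = I_e0
    ie = I_e0
    for i in range(n - 1):
        h = times[i + 1] - times[i]
        c = I_v[i]
        d = (I_v[i + 1] - I_v[i]) / h
        if b > 0:
            # particular solution p(tau) = (a c)/b - a d / b^2 + (a d / b) tau
            p0 = a * c / b - a * d / (b * b)
            e = math.exp(-b * h)
            ie = p0 + (a * d / b) * h + (ie - p0) * e
        else:
            ie = ie + a * (c + 0.5 * d * h) * h
        out[i + 1] = ie
    return out


def simulate_uptake_intensity(trace_times, I_v, PS: float, k_av: float,
                              v_e: float, Hct_mv: float = DEFAULT_HCT_MV,
                              I_e0: float = 0.0) -> np.ndarray:
    """Forward model of the extravascular intensity for given (PS, k_av)."""
    a = PS / (v_e * (1.0 - Hct_mv))
    b = PS / (v_e * k_av)
    return _integrate_uptake(np.asarray(trace_times, float),
                             np.asarray(I_v, float), a, b, I_e0)


def fit_permeability(
    trace: FluorescenceTrace,
    v_e: float,
    Hct_mv: float = DEFAULT_HCT_MV,
) -> tuple[float, float, dict]:
    """Estimate (PS, k_av) from intra-/extravascular fluorescence.

    Forward-simulates the intensity-space uptake equation with the
    observed ``I_v`` linearly interpolated and minimizes the squared
    residuals to the observed ``I_e`` over ``(PS, k_av)`` (unconstrained
    in log space, which enforces positivity).  Returns point estimates
    and a diagnostics dict with the residual norm.
    """
    t, iv, ie = trace.times, trace.I_v, trace.I_e
    iv_peak = float(np.max(np.abs(iv)))
    if iv_peak <= 0 or np.allclose(iv, 0.0):
        raise EstimationError(
            "intravascular signal is identically zero; PS is unidentifiable")

    # data-driven initializers: early slope gives PS/(v_e (1-Hct)),
    # late-time intensity ratio I_e/I_v -> k_av (1-Hct) at equilibrium
    n_early = max(3, t.size // 10)
    slope0 = np.polyfit(t[:n_early], ie[:n_early], 1)[0]
    a0 = max(slope0, 1e-9) / max(np.mean(iv[:n_early]), 1e-12 * iv_peak)
    PS0 = max(a0 * v_e * (1.0 - Hct_mv), 1e-6)
    ratio = ie[-1] / iv[-1] if iv[-1] > 0 else 0.5
    k_av0 = min(max(ratio * (1.0 - Hct_mv), 0.05), 1.5)

    def resid(logp):
        PS, k_av = np.exp(logp)
        return simulate_uptake_intensity(t, iv, PS, k_av, v_e, Hct_mv,
                                         I_e0=ie[0]) - ie

    best = None
    for x0 in ([math.log(PS0), math.log(k_av0)],
               [math.log(PS0 * 5), math.log(0.5)],
               [math.log(max(PS0 / 5, 1e-8)), math.log(0.9)]):
        try:
            res = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise EstimationError("permeability fit failed to converge")
    PS, k_av = np.exp(best.x)
    if k_av < 1e-4:
        raise EstimationError(
            f"available-fraction estimate collapsed to k_av={k_av:.2e}")
    diagnostics = {
        "residual_norm": float(np.linalg.norm(best.fun)),
        "cost": float(best.cost),
        "n_points": int(t.size),
        "initial": {"PS": PS0, "k_av": k_av0},
    }
    return float(PS), float(k_av), diagnostics


# ---------------------------------------------------------------------------
# transit time


def estimate_transit_time(trace: FluorescenceTrace, window: float = 30.0) -> float:
    """Microvascular transit time from the early bolus-arrival signal.

    With a rapid bolus the arterial input is a step, so the tissue
    intravascular signal is the step response of the washout residue;
    assuming exponential washout,
    ``I_v(t) = A (1 - exp(-(t - t0)/TT))`` for ``t >= t0`` (0 before).
    Least squares over ``(A, t0, TT)`` on the first ``window`` seconds.
    """
    mask = trace.times <= trace.times[0] + window
    t, iv = trace.times[mask], trace.I_v[mask]
    peak = float(np.max(iv))
    if peak <= 0 or iv[-1] <= iv[0] + 1e-12 * max(peak, 1.0):
        raise EstimationError("intravascular signal does not rise; cannot "
                              "estimate a transit time")

    # initializers: arrival where signal crosses 5% of peak; TT from 63% rise
    above = np.nonzero(iv >= 0.05 * peak)[0]
    t0_0 = t[above[0]] if above.size else t[0]
    r63 = np.nonzero(iv >= 0.632 * peak)[0]
    TT0 = max((t[r63[0]] - t0_0) if r63.size else (t[-1] - t0_0) / 3.0, 1e-2)

    def model(p, tt_):
        A, t0, TT = p
        out = A * (1.0 - np.exp(-np.maximum(tt_ - t0, 0.0) / TT))
        return out

    def resid(p):
        return model(p, t) - iv

    res = least_squares(resid, [peak, t0_0, TT0],
                        bounds=([0.0, t[0] - window, 1e-4],
                                [10 * peak, t[-1], 10 * window]),
                        xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise EstimationError("transit-time fit failed to converge")
    TT = float(res.x[2])
    return TT


# ---------------------------------------------------------------------------
# systemic pharmacokinetics


def fit_biexponential(samples: BloodSampleSeries) -> Biexponential:
    """Nonlinear least squares of the bi-exponential decay (log residuals).

    Initialized by peel-off: a log-linear fit of the tail gives the slow
    phase, subtracting it and fitting the remainder gives the fast
    phase.  Warns when the two phases are not distinguishable.
    """
    t, c = samples.times, samples.concentration
    if t.size < 4:
        raise InputError("need >= 4 samples for a bi-exponential fit")
    if np.any(c <= 0):
        raise InputError("concentrations must be > 0 for a log-space fit")

    # peel-off initializer
    n_tail = max(2, t.size // 2)
    slow = np.polyfit(t[-n_tail:], np.log(c[-n_tail:]), 1)
    l2_0 = max(-slow[0], 1e-9)
    tail = np.exp(slow[1] - l2_0 * t)
    head = c - tail
    pos = head > 0
    if np.count_nonzero(pos[: max(2, t.size // 2)]) >= 2:
        fast = np.polyfit(t[pos][:n_tail], np.log(head[pos][:n_tail]), 1)
        l1_0 = max(-fast[0], 2 * l2_0)
        A1_0 = math.exp(fast[1])
    else:
        l1_0, A1_0 = 10 * l2_0, 0.5 * c[0]
    C0_0 = A1_0 + math.exp(slow[1])
    alpha_0 = min(max(A1_0 / C0_0, 0.05), 0.95)

    def resid(p):
        logC0, za, logl1, logl2 = p
        C0 = math.exp(logC0)
        alpha = 1.0 / (1.0 + math.exp(-za))   # logistic keeps alpha in (0,1)
        l1, l2 = math.exp(logl1), math.exp(logl2)
        model = C0 * (alpha * np.exp(-l1 * t) + (1 - alpha) * np.exp(-l2 * t))
        return np.log(model) - np.log(c)

    x0 = [math.log(C0_0), math.log(alpha_0 / (1 - alpha_0)),
          math.log(l1_0), math.log(l2_0)]
    res = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        max_nfev=20000)
    if not res.success:
        raise EstimationError(f"bi-exponential fit failed: {res.status}")
    C0 = math.exp(res.x[0])
    alpha = 1.0 / (1.0 + math.exp(-res.x[1]))
    l1, l2 = math.exp(res.x[2]), math.exp(res.x[3])
    fit = Biexponential(C0=C0, alpha=alpha, lambda1=l1, lambda2=l2)
    if fit.lambda1 / fit.lambda2 < 1.02 or fit.alpha > 0.999 or fit.alpha < 1e-3:
        warnings.warn(
            "bi-exponential fit is nearly degenerate (mono-exponential data); "
            "the second phase is unidentifiable", stacklevel=2)
    return fit


def rate_constants(fit: Biexponential) -> tuple[float, float, float]:
    """Macro-to-micro conversion of the bi-exponential constants.

    Returns ``(k_t, k_p, k_e)`` with

    * ``k_t = alpha (1-alpha) (lambda2 - lambda1)^2 / ((1-alpha) lambda1 + alpha lambda2)``
    * ``k_p = (1-alpha) lambda1 + alpha lambda2``
    * ``k_e = lambda1 lambda2 / ((1-alpha) lambda1 + alpha lambda2)``

    In the usual micro-constant conventions (central-compartment dosing)
    ``k_p`` here is the tissue-to-plasma constant k21, ``k_t`` the
    plasma-to-tissue constant k12 and ``k_e`` the elimination constant
    k10; see docs/methods.md for how these names map onto the
    compartment equations.
    """
    a, l1, l2 = fit.alpha, fit.lambda1, fit.lambda2
    denom = (1.0 - a) * l1 + a * l2
    if denom == 0:
        raise EstimationError("degenerate kinetics: zero denominator in Eq. mapping")
    k_t = a * (1.0 - a) * (l2 - l1) ** 2 / denom
    k_p = denom
    k_e = l1 * l2 / denom
    return k_t, k_p, k_e


def biexponential_from_rate_constants(k_t: float, k_p: float, k_e: float,
                                      C0: float = 1.0) -> Biexponential:
    """Exact inverse of :func:`rate_constants` (closed-form forward model).

    For the two-compartment system with central dosing,
    ``dc_p/dt = -(k_e + k_t) c_p + k_p c_t`` and
    ``dc_t/dt = k_t c_p - k_p c_t`` (``k_t`` plasma->tissue, ``k_p``
    tissue->plasma, matching :func:`rate_constants`), the plasma curve is
    bi-exponential with eigenvalues from
    ``l^2 - (k_e + k_t + k_p) l + k_e k_p = 0``.
    """
    if min(k_t, k_p, k_e) < 0:
        raise InvalidParameterError("rate constants must be >= 0")
    tr = k_e + k_t + k_p
    det = k_e * k_p
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    if l1 == l2:
        alpha = 1.0
    else:
        alpha = (k_e + k_t - l2) / (l1 - l2)
    return Biexponential(C0=C0, alpha=alpha, lambda1=l1, lambda2=l2)


def initial_distribution_volume(sample_conc_at_2min: float, ID: float) -> float:
    """Initial volume of distribution ``V_D = ID / C(2 min)`` (mL)."""
    if not sample_conc_at_2min > 0:
        raise InputError("first-sample concentration must be > 0")
    if not ID > 0:
        raise InvalidParameterError("injected dose must be > 0")
    return ID / sample_conc_at_2min


# ---------------------------------------------------------------------------
# fluorescence -> concentration


def fluorescence_to_concentration(
    trace: FluorescenceTrace,
    calib: CalibrationSpec,
    mode: str = "free",
    baseline_I_v: Optional[float] = None,
    baseline_concentration: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert intensity traces to (plasma, EES) concentration traces.

    ``free`` mode: direct calibration with the available volume
    fractions, ``c_p = scale I_v / (1 - Hct_mv)`` and
    ``c_e = scale I_e / k_av``.

    ``tsl`` mode: the pre-release intravascular baseline ``baseline_I_v``
    comes from quenched encapsulated dye at the known encapsulated
    plasma concentration ``baseline_concentration``; released free dye
    is brighter by the dequench factor D, so

    ``c_released = c_enc (I_v - I_base) / ((D - 1) I_base)``

    (0 at the baseline, the full encapsulated concentration at complete
    local release ``I_v = D I_base``).  The EES conversion uses the same
    per-molecule brightness: ``c_e = I_e (1-Hct) c_enc / (D I_base k_av)``.
    """
    if mode == "free":
        c_p = calib.scale * trace.I_v / (1.0 - calib.Hct_mv)
        c_e = calib.scale * trace.I_e / calib.k_av
        return c_p, c_e
    if mode != "tsl":
        raise InvalidParameterError("mode must be 'free' or 'tsl'")
    if baseline_I_v is None or baseline_concentration is None:
        raise CalibrationError(
            "tsl mode requires the pre-release intravascular baseline "
            "intensity and the encapsulated plasma concentration")
    if baseline_I_v <= 0:
        raise CalibrationError("baseline intensity must be > 0")
    D = calib.dequench_factor
    c_enc = baseline_concentration
    c_p_released = c_enc * (trace.I_v - baseline_I_v) / ((D - 1.0) * baseline_I_v)
    gain_free = D * baseline_I_v / ((1.0 - calib.Hct_mv) * c_enc)
    c_e = trace.I_e / (gain_free * calib.k_av)
    return c_p_released, c_e
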